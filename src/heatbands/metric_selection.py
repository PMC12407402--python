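"""Two-stage preferred-metric selection over a set of fitted models.

Stage one screens each candidate metric by the joint-significance F test of
its heat regressors (cluster-robust Wald, at level ``alpha``); metrics
whose coefficients cannot be distinguished from zero jointly are set
aside.  Stage two ranks survivors by AIC (lower is better), reporting the
within adjusted R-squared alongside and flagging loudly when the two
measures disagree on the winner.  Ties break on fewer regressors, then
metric name.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from .fe_model import FEFit, joint_wald_F

__all__ = ["SelectionReport", "screen_joint_significance", "rank_and_select"]

logger = logging.getLogger(__name__)


@dataclass
class SelectionReport:
    """Per-metric fit comparison and the selected preferred metric."""

    table: pd.DataFrame  # one row per candidate, Table-2-shaped
    preferred: str
    rationale: str

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def _metric_stats(name: str, fit: FEFit) -> dict:
    f, df1, df2, p = joint_wald_F(fit, name)
    return {
        "metric": name,
        "F": f,
        "df1": df1,
        "df2": df2,
        "p": p,
        "within_adj_r2": fit.within_adj_r2,
        "aic": fit.aic,
        "k_heat": df1,
    }


def screen_joint_significance(fits: dict[str, FEFit], alpha: float = 0.05) -> set[str]:
    """Metrics whose heat terms are jointly significant at level alpha."""
    if not fits:
        raise ValueError("no fitted models supplied")
    survivors = set()
    for name, fit in fits.items():
        _, _, _, p = joint_wald_F(fit, name)
        if p < alpha or alpha >= 1.0:
            survivors.add(name)
    return survivors


def rank_and_select(fits: dict[str, FEFit], alpha: float = 0.05) -> SelectionReport:
    """Screen, then rank survivors by AIC; report every candidate.

    The report table includes screened-out metrics with the reason, so the
    comparison is auditable; selection is invariant to the order in which
    fits are supplied.
    """
    survivors = screen_joint_significance(fits, alpha)
    rows = []
    for name in sorted(fits):
        row = _metric_stats(name, fits[name])
        row["screened_out"] = name not in survivors
        row["reason"] = "" if name in survivors else "failed joint F screen"
        rows.append(row)
    table = pd.DataFrame(rows)

    if not survivors:
        raise ValueError(f"no metric passed the joint-significance screen at alpha={alpha}")

    ranked = sorted(
        survivors, key=lambda m: (fits[m].aic, len(fits[m].heat_columns(m)), m)
    )
    preferred = ranked[0]
    best_r2 = max(survivors, key=lambda m: fits[m].within_adj_r2)
    if best_r2 != preferred:
        rationale = (
            f"AIC prefers {preferred!r} but within adjusted R2 prefers {best_r2!r}; "
            "AIC is the primary ranking key - DISAGREEMENT, inspect both models"
        )
        logger.warning(rationale)
    elif len(ranked) > 1 and fits[ranked[0]].aic == fits[ranked[1]].aic:
        rationale = (
            f"tie on AIC between {ranked[0]!r} and {ranked[1]!r}; broken by "
            "regressor count then name order"
        )
        logger.info(rationale)
    else:
        rationale = f"{preferred!r} has the lowest AIC among screened metrics"

    table["preferred"] = table["metric"] == preferred
    return SelectionReport(table=table, preferred=preferred, rationale=rationale)
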