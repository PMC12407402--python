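"""Counterfactual hottest-vs-coolest seasonal exposure predictions.

Two hypothetical cohorts are compared: one in which every pregnancy
experiences heat typical of the hottest nine months of the year (birth in
mid-May, in the Northern Territory calendar) and one typical of the coolest
nine months (birth in mid-November).  "Typical" is the multi-year
day-of-year climatology at each birth's own location.

The prediction is a partial-effect contrast: only the heat regressors are
swapped from their factual values to the scenario values, with covariates
and fixed effects held fixed - these cancel exactly in the scenario
difference, so the predicted cohort rate is the observed mean outcome plus
the mean change in the heat terms times their coefficients.  Confidence
intervals (68/80/95 %) cover the heat-coefficient-driven component only,
by the delta method on the cluster-robust covariance using Student-t
critical values with G - 1 degrees of freedom; a parametric-simulation
alternative draws coefficient vectors from their estimated distribution.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from datetime import date, timedelta

import numpy as np
import pandas as pd
from scipy import stats

from . import thermo
from .exposure import GESTATION_DAYS, MetricSpec, build_exposures
from .fe_model import FEFit

__all__ = [
    "SCENARIO_BIRTH_MONTH",
    "day_of_year_climatology",
    "climatology_series",
    "scenario_exposure",
    "predict_rates",
    "PredictionResult",
]

# Scenario label -> implied birth month: gestation ending mid-May spans the
# hottest nine months (the build-up and wet season); ending mid-November
# spans the coolest nine (the dry season).
SCENARIO_BIRTH_MONTH = {"hottest9": 5, "coolest9": 11}

CI_LEVELS = (0.68, 0.80, 0.95)


def day_of_year_climatology(
    weather: pd.DataFrame, reference_years: list[int] | None = None
) -> pd.DataFrame:
    """Per-location day-of-year means of the base daily fields.

    Only complete calendar years contribute (incomplete years are dropped
    with a warning); Feb 29 is filled from Feb 28.  Derived fields are NOT
    averaged - recompute them from the averaged base fields via
    :func:`heatbands.thermo.derive_daily_fields` on a materialised series.

    Returns a frame with columns location_id, month, day, tmax_c, tmin_c,
    rh_pct (366 rows per location).
    """
    w = weather.copy()
    w["date"] = pd.to_datetime(w["date"])
    w["year"] = w["date"].dt.year
    w["month"] = w["date"].dt.month
    w["day"] = w["date"].dt.day
    if reference_years is not None:
        w = w[w["year"].isin(reference_years)]
    profiles = []
    for loc, grp in w.groupby("location_id", sort=False):
        counts = grp.groupby("year")["date"].count()
        complete = [
            y for y, c in counts.items() if c >= (366 if _is_leap(y) else 365)
        ]
        dropped = sorted(set(counts.index) - set(complete))
        if dropped:
            import warnings

            warnings.warn(
                f"location {loc!r}: excluding incomplete years {dropped} "
                "from the climatology",
                stacklevel=2,
            )
        if not complete:
            raise ValueError(f"location {loc!r}: no complete reference year")
        sub = grp[grp["year"].isin(complete)]
        prof = (
            sub.groupby(["month", "day"])[["tmax_c", "tmin_c", "rh_pct"]]
            .mean()
            .reset_index()
        )
        if not ((prof["month"] == 2) & (prof["day"] == 29)).any():
            feb28 = prof[(prof["month"] == 2) & (prof["day"] == 28)].copy()
            feb28["day"] = 29
            prof = pd.concat([prof, feb28], ignore_index=True)
        prof = prof.sort_values(["month", "day"]).reset_index(drop=True)
        prof.insert(0, "location_id", loc)
        profiles.append(prof)
    return pd.concat(profiles, ignore_index=True)


def _is_leap(y: int) -> bool:
    return y % 4 == 0 and (y % 100 != 0 or y % 400 == 0)


def climatology_series(
    profile: pd.DataFrame, start: date, end: date
) -> pd.DataFrame:
    """Materialise a gap-free daily weather table over [start, end] by
    repeating the climatology, with derived fields recomputed."""
    dates = pd.date_range(start, end, freq="D")
    key = pd.DataFrame({"date": dates})
    key["month"] = key["date"].dt.month
    key["day"] = key["date"].dt.day
    frames = []
    for loc, prof in profile.groupby("location_id", sort=False):
        merged = key.merge(prof.drop(columns="location_id"), on=["month", "day"], how="left")
        merged.insert(0, "location_id", loc)
        frames.append(merged[["location_id", "date", "tmax_c", "tmin_c", "rh_pct"]])
    out = pd.concat(frames, ignore_index=True)
    return thermo.derive_daily_fields(out)


def scenario_exposure(
    profile: pd.DataFrame,
    scenario: str,
    metric_spec: MetricSpec,
    reference_year: int = 2005,
) -> pd.DataFrame:
    """Per-location exposure vectors under a seasonal scenario.

    The conception date is set so a 39-week gestation ends on the 15th of
    the scenario's birth month of ``reference_year``; exposure is computed
    from the location's climatology exactly as for real weather.  Returns
    one row per location, indexed by location_id.
    """
    if scenario not in SCENARIO_BIRTH_MONTH:
        raise ValueError(f"unknown scenario {scenario!r}; use one of {list(SCENARIO_BIRTH_MONTH)}")
    birth = date(reference_year, SCENARIO_BIRTH_MONTH[scenario], 15)
    conception = birth - timedelta(days=GESTATION_DAYS)
    # pad the materialised series enough for the EHF warm-up window
    series = climatology_series(
        profile, conception - timedelta(days=40), birth + timedelta(days=5)
    )
    locs = profile["location_id"].unique()
    pseudo = pd.DataFrame(
        {
            "birth_id": locs,
            "location_id": locs,
            "conception_date": [conception] * len(locs),
        }
    )
    expo = build_exposures(pseudo, series, metric_spec)
    expo.index.name = "location_id"
    expo.attrs["scenario"] = scenario
    return expo


@dataclass
class PredictionResult:
    """Predicted cohort preterm rates under the two scenarios.

    Rates are probabilities; the difference (hottest - coolest) is in the
    same units.  ``ci`` maps quantity -> level -> (lo, hi); rates are
    clipped to [0, 1] for reporting with ``clipped`` recording whether any
    clipping occurred.
    """

    rates: dict[str, float]
    difference: float
    ci: dict[str, dict[float, tuple[float, float]]]
    clipped: dict[str, bool] = dc_field(default_factory=dict)
    method: str = "delta"

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for qty in list(self.rates) + ["difference"]:
            val = self.difference if qty == "difference" else self.rates[qty]
            row = {"quantity": qty, "estimate": val, "clipped": self.clipped.get(qty, False)}
            for lev in sorted(self.ci.get(qty, {})):
                lo, hi = self.ci[qty][lev]
                row[f"lo{int(lev * 100)}"] = lo
                row[f"hi{int(lev * 100)}"] = hi
            rows.append(row)
        return pd.DataFrame(rows)


def _contrast(
    fit: FEFit,
    factual: pd.DataFrame,
    scenario_expo: pd.DataFrame,
    births: pd.DataFrame,
) -> np.ndarray:
    """Mean over births of (scenario - factual) heat regressors, aligned to
    the fit's retained heat columns."""
    cols = fit.heat_columns()
    missing = [c for c in cols if c not in scenario_expo.columns or c not in factual.columns]
    if missing:
        raise ValueError(f"exposure tables lack model heat columns: {missing}")
    xf = factual.loc[births["birth_id"], cols].to_numpy(dtype=float)
    xs = scenario_expo.loc[births["location_id"], cols].to_numpy(dtype=float)
    return (xs - xf).mean(axis=0)


def predict_rates(
    fit: FEFit,
    factual: pd.DataFrame,
    scenario_expos: dict[str, pd.DataFrame],
    births: pd.DataFrame,
    method: str = "delta",
    n_draws: int = 10_000,
    seed: int = 0,
) -> PredictionResult:
    """Predicted cohort rates under each scenario, their difference, and CIs.

    The predicted rate under scenario s is
    ``mean(y) + mean_i[(x_s,i - x_f,i)' b_heat]``; fixed effects and
    covariates cancel in the construction.  ``method`` selects delta-method
    CIs (default) or parametric simulation from N(b, V).
    """
    if set(scenario_expos) != {"hottest9", "coolest9"}:
        raise ValueError("scenario_expos must have exactly the keys 'hottest9' and 'coolest9'")
    cols = fit.heat_columns()
    if not cols:
        raise ValueError("fitted model has no heat terms to contrast")
    b = fit.params[cols].to_numpy()
    v = fit.vcov.loc[cols, cols].to_numpy()
    ybar = fit.y_mean

    contrasts = {
        s: _contrast(fit, factual, expo, births) for s, expo in scenario_expos.items()
    }
    c_diff = contrasts["hottest9"] - contrasts["coolest9"]

    raw_rates = {s: ybar + float(c @ b) for s, c in contrasts.items()}
    difference = float(c_diff @ b)

    tcrit = {lev: stats.t.ppf((1 + lev) / 2, fit.n_clusters - 1) for lev in CI_LEVELS}
    ci: dict[str, dict[float, tuple[float, float]]] = {}
    if method == "delta":
        for s, c in list(contrasts.items()) + [("difference", c_diff)]:
            se = float(np.sqrt(c @ v @ c))
            center = difference if s == "difference" else raw_rates[s]
            ci[s] = {lev: (center - tcrit[lev] * se, center + tcrit[lev] * se) for lev in CI_LEVELS}
    elif method == "simulation":
        rng = np.random.default_rng(seed)
        draws = rng.multivariate_normal(b, v, size=n_draws, method="cholesky")
        for s, c in list(contrasts.items()) + [("difference", c_diff)]:
            base = 0.0 if s == "difference" else ybar
            vals = base + draws @ c
            ci[s] = {
                lev: (
                    float(np.quantile(vals, (1 - lev) / 2)),
                    float(np.quantile(vals, (1 + lev) / 2)),
                )
                for lev in CI_LEVELS
            }
    else:
        raise ValueError("method must be 'delta' or 'simulation'")

    rates, clipped = {}, {}
    for s, r in raw_rates.items():
        rc = min(max(r, 0.0), 1.0)
        clipped[s] = rc != r
        rates[s] = rc
    return PredictionResult(
        rates=rates, difference=difference, ci=ci, clipped=clipped, method=method
    )


def plot_predictions(result: PredictionResult, ax=None):
    """Two predicted rates with nested 68/80/95 % CI bars."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    order = ["coolest9", "hottest9"]
    widths = {0.95: 1.0, 0.80: 2.5, 0.68: 4.5}
    for x, s in enumerate(order):
        for lev, lw in widths.items():
            lo, hi = result.ci[s][lev]
            ax.plot([x, x], [lo, hi], lw=lw, color="tab:red" if s == "hottest9" else "tab:blue")
        ax.plot(x, result.rates[s], "o", color="black")
    ax.set_xticks(range(len(order)))
    ax.set_xticklabels(order)
    ax.set_ylabel("predicted preterm birth rate")
    return ax
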