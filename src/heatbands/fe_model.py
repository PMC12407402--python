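"""Linear probability model with absorbed interacted fixed effects.

The estimating equation regresses a binary (or continuous) birth outcome on
per-trimester heat regressors and individual covariates, absorbing two
high-dimensional fixed-effect groups:

* location x month-of-conception x infant sex, and
* calendar month-year of conception,

via alternating within-group demeaning (the within transformation iterated
to convergence).  Inference is cluster-robust at the geographic-cluster
level with the Stata ``areg``-style small-sample factor
``G/(G-1) * (N-1)/(N-K)`` where K counts absorbed fixed effects as well as
regressors.  Joint significance of a heat-metric term group is assessed by
a Wald F test on the cluster-robust covariance with denominator degrees of
freedom G - 1.

Model-fit statistics: the "within" adjusted R-squared (computed on the
demeaned data, penalised for the non-absorbed regressor count) and a
Gaussian AIC whose parameter count excludes the absorbed fixed effects -
legitimate for ranking models that share an identical fixed-effect
structure, which is the only use made of it here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg
from scipy import stats

__all__ = [
    "ModelSpec",
    "Design",
    "FEFit",
    "build_design",
    "absorb_fixed_effects",
    "fit_within_ols",
    "cluster_robust_vcov",
    "joint_wald_F",
    "fit_statistics",
    "fit_fe_model",
]

AGE_BANDS = ("lt20", "20_24", "25_29", "30_34", "35_39", "ge40")
AGE_REFERENCE = "25_29"
COVARIATES = ("first_pregnancy", "aboriginal", "mother_age_band")


@dataclass(frozen=True)
class ModelSpec:
    """What to regress on what.

    ``heat_terms`` maps a metric name to the exposure columns it
    contributes (omitted reference bands already excluded); several metrics
    may be combined in one model by supplying several entries.
    """

    outcome: str = "preterm"
    heat_terms: dict[str, list[str]] = field(default_factory=dict)
    covariates: tuple[str, ...] = COVARIATES
    cluster: str = "geocluster_id"


@dataclass
class Design:
    """Aligned arrays ready for absorption and estimation."""

    y: np.ndarray
    X: pd.DataFrame
    fe_codes: list[np.ndarray]  # integer group codes, one array per FE group
    fe_levels: list[int]
    cluster_codes: np.ndarray
    heat_terms: dict[str, list[str]]
    n_dropped_rows: int


def _one_hot(series: pd.Series, reference: str, prefix: str) -> pd.DataFrame:
    levels = [l for l in pd.unique(series) if l != reference]
    levels = sorted(map(str, levels))
    out = {}
    for lev in levels:
        out[f"{prefix}_{lev}"] = (series.astype(str) == lev).astype(float)
    return pd.DataFrame(out, index=series.index)


def build_design(
    births: pd.DataFrame,
    exposures: pd.DataFrame | None,
    spec: ModelSpec,
    cluster_map: dict | None = None,
) -> Design:
    """Assemble outcome, regressor matrix, FE labels and cluster labels.

    ``births`` must carry the outcome, ``birth_id``, ``location_id``,
    ``sex``, a conception date (or birth_date + gestational_weeks), the
    covariates, and - unless ``cluster_map`` is given - a
    ``geocluster_id`` column.  Exposure columns named in
    ``spec.heat_terms`` are joined by ``birth_id``; omitted bands must not
    be named there.
    """
    df = births.reset_index(drop=True).copy()
    if "conception_date" not in df.columns:
        df["conception_date"] = pd.to_datetime(df["birth_date"]) - pd.to_timedelta(
            df["gestational_weeks"] * 7, unit="D"
        )
    conc = pd.to_datetime(df["conception_date"])

    heat_cols: list[str] = [c for cols in spec.heat_terms.values() for c in cols]
    if len(set(heat_cols)) != len(heat_cols):
        raise ValueError("duplicate heat regressor names across term groups")
    if heat_cols:
        if exposures is None:
            raise ValueError("heat terms requested but no exposure table supplied")
        omitted = set(exposures.attrs.get("omitted", []))
        banned = omitted.intersection(heat_cols)
        if banned:
            raise ValueError(f"omitted reference bands may not enter the design: {sorted(banned)}")
        missing = [c for c in heat_cols if c not in exposures.columns]
        if missing:
            raise ValueError(f"exposure columns not found: {missing}")
        xh = exposures.loc[df["birth_id"], heat_cols].reset_index(drop=True)
    else:
        xh = pd.DataFrame(index=df.index)

    xc_parts = []
    for cov in spec.covariates:
        if cov not in df.columns:
            raise ValueError(f"covariate {cov!r} missing from births table")
        if cov == "mother_age_band":
            xc_parts.append(_one_hot(df[cov], AGE_REFERENCE, "age"))
        else:
            xc_parts.append(df[[cov]].astype(float))
    X = pd.concat([xh] + xc_parts, axis=1)

    y = df[spec.outcome].to_numpy(dtype=float)
    if np.all(y == y[0]):
        raise ValueError(f"outcome {spec.outcome!r} has zero variance")

    month = conc.dt.month.astype(str)
    ym = conc.dt.to_period("M").astype(str)
    fe1 = (
        df["location_id"].astype(str) + "|m" + month + "|s" + df["sex"].astype(str)
    )
    fe2 = ym

    if cluster_map is not None:
        cl = df["location_id"].map(cluster_map)
        if cl.isna().any():
            raise ValueError("cluster_map does not cover all locations")
    elif spec.cluster in df.columns:
        cl = df[spec.cluster]
    else:
        raise ValueError(f"no cluster labels: column {spec.cluster!r} absent and no cluster_map")

    keep = ~(X.isna().any(axis=1) | pd.isna(y) | cl.isna())
    n_dropped = int((~keep).sum())
    X = X.loc[keep]
    y = y[keep.to_numpy()]
    fe1 = fe1.loc[keep]
    fe2 = fe2.loc[keep]
    cl = cl.loc[keep]

    codes1, lev1 = pd.factorize(fe1)
    codes2, lev2 = pd.factorize(fe2)
    clcodes, _ = pd.factorize(cl)
    return Design(
        y=y,
        X=X.reset_index(drop=True),
        fe_codes=[codes1, codes2],
        fe_levels=[len(lev1), len(lev2)],
        cluster_codes=clcodes,
        heat_terms=spec.heat_terms,
        n_dropped_rows=n_dropped,
    )


def _demean_once(values: np.ndarray, codes: np.ndarray, n_groups: int) -> np.ndarray:
    """Subtract group means in place-free fashion; values is (n,) or (n, k)."""
    counts = np.bincount(codes, minlength=n_groups).astype(float)
    if values.ndim == 1:
        sums = np.bincount(codes, weights=values, minlength=n_groups)
        return values - (sums / counts)[codes]
    out = values.copy()
    for j in range(values.shape[1]):
        sums = np.bincount(codes, weights=values[:, j], minlength=n_groups)
        out[:, j] = values[:, j] - (sums / counts)[codes]
    return out


def absorb_fixed_effects(
    y: np.ndarray,
    X: np.ndarray,
    fe_codes: list[np.ndarray],
    fe_levels: list[int] | None = None,
    tol: float = 1e-10,
    max_sweeps: int = 10_000,
) -> tuple[np.ndarray, np.ndarray, int]:
    """Within transformation: project out all FE groups by alternating
    within-group demeaning, iterated until the largest absolute change in
    any entry falls below ``tol``.

    Returns demeaned (y, X) and the number of sweeps taken.  With a single
    FE group one sweep is exact.  Raises on non-convergence.
    """
    if not fe_codes:
        raise ValueError("at least one fixed-effect group is required")
    if fe_levels is None:
        fe_levels = [int(c.max()) + 1 for c in fe_codes]
    Z = np.column_stack([np.asarray(y, dtype=float), np.asarray(X, dtype=float)])
    if len(fe_codes) == 1:
        Z = _demean_once(Z, fe_codes[0], fe_levels[0])
        return Z[:, 0], Z[:, 1:], 1
    for sweep in range(1, max_sweeps + 1):
        prev = Z
        for codes, ng in zip(fe_codes, fe_levels):
            Z = _demean_once(Z, codes, ng)
        delta = np.abs(Z - prev).max() if Z.size else 0.0
        if delta < tol:
            return Z[:, 0], Z[:, 1:], sweep
    raise RuntimeError(
        f"fixed-effect absorption did not converge in {max_sweeps} sweeps "
        f"(last max change {delta:.3e} > tol {tol:.1e})"
    )


@dataclass
class FEFit:
    """A fitted within-regression with cluster-robust covariance."""

    params: pd.Series
    vcov: pd.DataFrame
    resid: np.ndarray
    n_obs: int
    n_clusters: int
    rss: float
    tss_within: float
    k: int  # retained non-absorbed regressors
    df_absorbed: int
    dropped: list[str]
    heat_terms: dict[str, list[str]]
    y_mean: float
    within_r2: float = np.nan
    within_adj_r2: float = np.nan
    aic: float = np.nan
    n_sweeps: int = 0

    @property
    def bse(self) -> pd.Series:
        return pd.Series(np.sqrt(np.diag(self.vcov)), index=self.params.index)

    def heat_columns(self, group: str | None = None) -> list[str]:
        if group is None:
            cols = [c for cols in self.heat_terms.values() for c in cols]
        else:
            cols = list(self.heat_terms[group])
        return [c for c in cols if c in self.params.index]

    def coef_table(self) -> pd.DataFrame:
        return pd.DataFrame({"coef": self.params, "se": self.bse})


def fit_within_ols(
    yd: np.ndarray,
    Xd: np.ndarray,
    columns: list[str],
    rcond: float = 1e-9,
) -> tuple[np.ndarray, np.ndarray, list[int], list[str]]:
    """Least squares on demeaned data with pivoted-QR collinearity handling.

    Returns (coefficients over kept columns, residuals, kept column
    positions, dropped column names).  Columns demeaned to (numerically)
    zero or exactly collinear with earlier ones are dropped and logged.
    """
    Xd = np.asarray(Xd, dtype=float)
    if Xd.shape[1] == 0:
        return np.empty(0), yd.copy(), [], []
    q, r, piv = scipy.linalg.qr(Xd, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    ref = diag[0] if diag.size and diag[0] > 0 else 1.0
    rank = int(np.sum(diag > rcond * max(ref, 1.0)))
    if rank == 0:
        raise ValueError("design has rank 0 after fixed-effect absorption")
    keep = sorted(piv[:rank].tolist())
    dropped = [columns[i] for i in sorted(piv[rank:].tolist())]
    Xk = Xd[:, keep]
    beta, *_ = np.linalg.lstsq(Xk, yd, rcond=None)
    resid = yd - Xk @ beta
    return beta, resid, keep, dropped


def cluster_robust_vcov(
    Xd: np.ndarray,
    resid: np.ndarray,
    cluster_codes: np.ndarray,
    k_total: int,
) -> np.ndarray:
    """Cluster-robust sandwich covariance with areg-style finite-sample factor.

    ``k_total`` is the full parameter count K including absorbed fixed
    effects; the factor is ``G/(G-1) * (N-1)/(N-K)``.  With every
    observation its own cluster this reduces to the HC1-style robust
    sandwich up to the same factors.
    """
    g = int(cluster_codes.max()) + 1 if len(cluster_codes) else 0
    if g < 2:
        raise ValueError("cluster-robust covariance requires at least 2 clusters")
    n, k = Xd.shape
    bread = np.linalg.inv(Xd.T @ Xd)
    scores = Xd * resid[:, None]
    su = np.zeros((g, k))
    for j in range(k):
        su[:, j] = np.bincount(cluster_codes, weights=scores[:, j], minlength=g)
    meat = su.T @ su
    factor = (g / (g - 1)) * ((n - 1) / (n - k_total))
    return factor * bread @ meat @ bread


def joint_wald_F(fit: FEFit, term_group: str) -> tuple[float, int, int, float]:
    """Wald F test that all coefficients in one heat term group are zero.

    F = b' V^-1 b / q on the cluster-robust covariance, with numerator
    degrees of freedom q (the number of tested terms) and denominator
    degrees of freedom G - 1.
    """
    cols = fit.heat_columns(term_group)
    if not cols:
        raise ValueError(f"term group {term_group!r} has no retained columns")
    b = fit.params[cols].to_numpy()
    v = fit.vcov.loc[cols, cols].to_numpy()
    try:
        w = float(b @ np.linalg.solve(v, b))
    except np.linalg.LinAlgError:
        warnings.warn("singular sub-covariance in joint Wald test; using pseudo-inverse")
        w = float(b @ np.linalg.pinv(v) @ b)
    df1 = len(cols)
    df2 = fit.n_clusters - 1
    f = w / df1
    p = float(stats.f.sf(f, df1, df2))
    return f, df1, df2, p


def fit_statistics(fit: FEFit, include_absorbed_in_aic: bool = False) -> tuple[float, float]:
    """(within adjusted R-squared, AIC) for a fitted model.

    Within R2 is computed on the demeaned data; the adjustment uses the
    absorbed-FE-corrected effective sample size.  The Gaussian AIC counts
    the retained regressors, an intercept and the error variance; absorbed
    fixed effects are excluded unless ``include_absorbed_in_aic`` (their
    count is identical across the models being ranked).
    """
    if fit.rss <= 0:
        raise ValueError("zero residual variance: AIC undefined")
    n = fit.n_obs
    r2 = 1.0 - fit.rss / fit.tss_within
    n_eff = n - fit.df_absorbed
    denom = n_eff - fit.k - 1
    adj = 1.0 - (1.0 - r2) * (n_eff - 1) / denom if denom > 0 else np.nan
    p = fit.k + 2 + (fit.df_absorbed if include_absorbed_in_aic else 0)
    ll = -0.5 * n * (np.log(2 * np.pi) + np.log(fit.rss / n) + 1.0)
    aic = -2.0 * ll + 2.0 * p
    return float(adj), float(aic)


class WithinSolver:
    """Absorb and factorise a design once; refit for any outcome vector.

    Replicate simulations redraw the outcome while the regressors, fixed
    effects and clusters stay fixed; demeaning the regressor matrix and
    taking its QR decomposition are then one-off costs.
    """

    def __init__(self, design: Design, tol: float = 1e-10):
        self.design = design
        self.tol = tol
        cols = list(design.X.columns)
        zero = np.zeros(len(design.y))
        _, Xd, self.n_sweeps = absorb_fixed_effects(
            zero, design.X.to_numpy(dtype=float), design.fe_codes, design.fe_levels, tol=tol
        )
        if Xd.shape[1]:
            _, _, keep, dropped = fit_within_ols(Xd[:, 0] * 0.0, Xd, cols)
        else:
            keep, dropped = [], []
        self.keep = keep
        self.dropped = dropped
        self.kept_cols = [cols[i] for i in keep]
        self.Xk = Xd[:, keep]
        if self.Xk.shape[1]:
            self._q, self._r = np.linalg.qr(self.Xk)
        self.df_absorbed = sum(design.fe_levels) - (len(design.fe_levels) - 1)
        self.g = int(design.cluster_codes.max()) + 1

    def fit(self, y: np.ndarray | None = None) -> FEFit:
        design = self.design
        y = design.y if y is None else np.asarray(y, dtype=float)
        yd, _, _ = absorb_fixed_effects(
            y, np.empty((len(y), 0)), design.fe_codes, design.fe_levels, tol=self.tol
        )
        if self.Xk.shape[1]:
            beta = scipy.linalg.solve_triangular(self._r, self._q.T @ yd)
            resid = yd - self.Xk @ beta
        else:
            beta = np.empty(0)
            resid = yd.copy()
        n = len(yd)
        k_total = len(self.keep) + self.df_absorbed
        if len(self.keep):
            v = cluster_robust_vcov(self.Xk, resid, design.cluster_codes, k_total)
        else:
            v = np.empty((0, 0))
        rss = float(resid @ resid)
        tss = float(yd @ yd)
        fit = FEFit(
            params=pd.Series(beta, index=self.kept_cols),
            vcov=pd.DataFrame(v, index=self.kept_cols, columns=self.kept_cols),
            resid=resid,
            n_obs=n,
            n_clusters=self.g,
            rss=rss,
            tss_within=tss,
            k=len(self.keep),
            df_absorbed=self.df_absorbed,
            dropped=self.dropped,
            heat_terms=design.heat_terms,
            y_mean=float(y.mean()),
            n_sweeps=self.n_sweeps,
        )
        fit.within_r2 = 1.0 - rss / tss if tss > 0 else np.nan
        fit.within_adj_r2, fit.aic = fit_statistics(fit)
        return fit


def fit_fe_model(design: Design, tol: float = 1e-10) -> FEFit:
    """Absorb, estimate, and attach cluster-robust covariance and fit stats."""
    return WithinSolver(design, tol=tol).fit()
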