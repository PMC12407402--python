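"""Synthetic weather and birth-cohort generator with known ground truth.

The real study population (administrative perinatal records linked to
reanalysis weather) is confidential, so every downstream stage is exercised
on synthetic data that emulates its salient features:

* two climate zones - a tropical zone whose average wet-season day spans
  roughly 25-33 degC and dry-season day 20-30 degC, and an arid zone with
  summer days of 20-35 degC and winter days of 4-20 degC;
* a much weaker correlation between daily maximum and minimum temperature
  in the tropical zone than the arid zone (achieved by giving the diurnal
  range its own noise), and a negative day-to-day correlation between
  humidity and temperature in the tropics;
* a ~10 % baseline preterm rate, with a configurable band-coefficient
  linear data-generating process linking per-trimester exposure-day counts
  to preterm risk, so model estimates can be checked against exact truth.

Weather model: daily maximum temperature is an annual sinusoid plus AR(1)
Gaussian noise; the diurnal range is itself seasonal plus independent
noise, and tmin = tmax - range.  Relative humidity is a seasonal curve
plus a coupling term proportional to the day's temperature anomaly (the
``rh_temp_coupling`` sign controls the humidity-temperature correlation),
clipped to [0, 100].
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from datetime import date, timedelta

import numpy as np
import pandas as pd

from .exposure import METRICS, MetricSpec, build_exposures, conception_date
from .fe_model import AGE_BANDS
from .geocluster import GeoPoint

__all__ = [
    "ClimateZoneParams",
    "TROPICAL",
    "ARID",
    "CohortDGP",
    "TruthRecord",
    "gen_weather",
    "gen_cohort",
    "apply_exclusions",
    "default_locations",
]

DAYS_PER_YEAR = 365.25


@dataclass(frozen=True)
class ClimateZoneParams:
    """Parameters of one climate zone's weather process (degC, %, days)."""

    zone_label: str
    tmax_mean_annual: float
    tmax_seasonal_amplitude: float
    diurnal_range_mean: float
    diurnal_range_seasonal_amplitude: float
    noise_sd_max: float
    noise_sd_range: float
    ar1_coefficient: float
    rh_mean: float
    rh_seasonal_amplitude: float
    rh_temp_coupling: float
    peak_day_of_year: int

    def __post_init__(self):
        if self.noise_sd_max < 0 or self.noise_sd_range < 0:
            raise ValueError("noise standard deviations must be non-negative")
        if not (0 <= self.ar1_coefficient < 1):
            raise ValueError("ar1_coefficient must lie in [0, 1)")
        if self.diurnal_range_mean <= 0:
            raise ValueError("diurnal_range_mean must be positive")
        if not (0 <= self.rh_mean <= 100):
            raise ValueError("rh_mean must lie in [0, 100]")


# Tropical zone: warm year-round, small seasonal cycle peaking at the
# build-up/wet season (early December), noisy diurnal range (weak
# tmax-tmin correlation), humidity anti-correlated with hot anomalies.
TROPICAL = ClimateZoneParams(
    zone_label="tropical",
    tmax_mean_annual=30.0,
    tmax_seasonal_amplitude=1.5,
    diurnal_range_mean=5.25,
    diurnal_range_seasonal_amplitude=-1.25,
    noise_sd_max=1.0,
    noise_sd_range=1.6,
    ar1_coefficient=0.55,
    rh_mean=72.0,
    rh_seasonal_amplitude=6.0,
    rh_temp_coupling=-8.0,
    peak_day_of_year=335,
)

# Arid zone: large seasonal cycle peaking mid-January, stable diurnal
# range (tmax and tmin move together), low humidity.
ARID = ClimateZoneParams(
    zone_label="arid",
    tmax_mean_annual=27.5,
    tmax_seasonal_amplitude=7.5,
    diurnal_range_mean=15.5,
    diurnal_range_seasonal_amplitude=-0.5,
    noise_sd_max=2.5,
    noise_sd_range=0.5,
    ar1_coefficient=0.6,
    rh_mean=35.0,
    rh_seasonal_amplitude=10.0,
    rh_temp_coupling=-1.0,
    peak_day_of_year=15,
)

ZONES = {"tropical": TROPICAL, "arid": ARID}

# Reference planted-truth effect profile for the max-and-min metric:
# a cooler-protective / hotter-risky gradient over daily-minimum and
# daily-maximum bands, a fraction of a percentage point of preterm risk per
# exposure day, consistent in scale with reported band-coefficient
# estimates in this literature.  Used by the identification experiments
# (parameter recovery, selection consistency).
MODERATE_BAND_EFFECTS = {
    "min_ge25_t1": 0.006,
    "min_ge25_t2": 0.006,
    "min_ge25_t3": 0.006,
    "min_lt5_t2": -0.005,
    "min_5_10_t2": -0.004,
    "max_35_40_t2": 0.004,
    "max_35_40_t3": 0.005,
    "max_lt20_t2": -0.004,
}

DEFAULT_COVARIATE_EFFECTS = {"first_pregnancy": 0.01, "aboriginal": 0.02}


def default_locations(
    n_tropical: int = 50, n_arid: int = 50, seed: int = 0
) -> tuple[list[GeoPoint], dict[str, str]]:
    """Synthetic geocoded locations: tropical points scattered over the Top
    End, arid points over the Centre.  Returns (points, zone map).

    The scatter is wide enough that most locations land in distinct
    50-mile clusters, giving a cluster count comfortably above the largest
    heat-metric term group (30 regressors) as required for a full-rank
    cluster-robust Wald test.
    """
    rng = np.random.default_rng([seed, 901])
    pts, zones = [], {}
    for i in range(n_tropical):
        lid = f"trop{i:02d}"
        pts.append(
            GeoPoint(lid, -13.0 + rng.uniform(-2.5, 2.5), 132.5 + rng.uniform(-4.5, 4.5))
        )
        zones[lid] = "tropical"
    for i in range(n_arid):
        lid = f"arid{i:02d}"
        pts.append(
            GeoPoint(lid, -22.0 + rng.uniform(-3.5, 3.5), 133.9 + rng.uniform(-4.5, 4.5))
        )
        zones[lid] = "arid"
    return pts, zones


def _seasonal(doy: np.ndarray, mean: float, amplitude: float, peak: int) -> np.ndarray:
    return mean + amplitude * np.cos(2 * np.pi * (doy - peak) / DAYS_PER_YEAR)


def gen_weather(
    params: ClimateZoneParams,
    locations: list[GeoPoint] | list[str],
    dates: tuple[date, date],
    seed: int,
) -> pd.DataFrame:
    """Gap-free daily weather for each location under one zone's parameters.

    ``dates`` is an inclusive (start, end) interval.  Identical
    (params, locations, dates, seed) give byte-identical output; each
    location gets an independent noise substream.
    """
    start, end = dates
    if end < start:
        raise ValueError("empty date interval")
    if not locations:
        raise ValueError("empty location list")
    loc_ids = [p.location_id if isinstance(p, GeoPoint) else str(p) for p in locations]

    drange = pd.date_range(start, end, freq="D")
    doy = drange.dayofyear.to_numpy()
    n = len(drange)
    s_max = _seasonal(doy, params.tmax_mean_annual, params.tmax_seasonal_amplitude, params.peak_day_of_year)
    s_rng = _seasonal(
        doy, params.diurnal_range_mean, params.diurnal_range_seasonal_amplitude, params.peak_day_of_year
    )
    s_rh = _seasonal(doy, params.rh_mean, params.rh_seasonal_amplitude, params.peak_day_of_year)

    frames = []
    for i, lid in enumerate(loc_ids):
        rng = np.random.default_rng([seed, 101, i])
        phi = params.ar1_coefficient
        z = rng.standard_normal(n)
        eps = np.empty(n)
        # stationary AR(1) with marginal sd = noise_sd_max
        eps[0] = z[0] * params.noise_sd_max
        innov_sd = params.noise_sd_max * np.sqrt(1 - phi**2)
        for t in range(1, n):
            eps[t] = phi * eps[t - 1] + innov_sd * z[t]
        tmax = s_max + eps
        rng_noise = rng.standard_normal(n) * params.noise_sd_range
        diurnal = np.maximum(s_rng + rng_noise, 0.0)
        tmin = tmax - diurnal
        rh = (
            s_rh
            + params.rh_temp_coupling * (tmax - s_max)
            + rng.standard_normal(n) * 3.0
        )
        rh = np.clip(rh, 0.0, 100.0)
        frames.append(
            pd.DataFrame(
                {
                    "location_id": lid,
                    "date": drange,
                    "tmax_c": tmax,
                    "tmin_c": tmin,
                    "rh_pct": rh,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


@dataclass
class CohortDGP:
    """Ground-truth data-generating process for the birth cohort.

    ``band_effects`` maps exposure regressor names (e.g. ``min_ge25_t2``)
    of ``metric`` to per-day effects on the preterm probability;
    ``covariate_effects`` likewise for covariates.  Latent probabilities
    are clipped to [0, 1] and the clipping frequency is reported in the
    :class:`TruthRecord`.
    """

    baseline_preterm_rate: float = 0.10
    metric: str = "max_and_min"
    band_effects: dict[str, float] = field(default_factory=dict)
    covariate_effects: dict[str, float] = field(default_factory=dict)
    n_births: int = 10_000
    conception_range: tuple[date, date] = (date(2001, 1, 1), date(2003, 12, 31))
    preterm_weeks: tuple[int, int] = (28, 36)
    term_weeks: tuple[int, int] = (37, 42)
    link: str = "linear"  # or "logistic", for robustness experiments
    # How the latent model's fixed-effect terms are set.  "cell" gives each
    # location x conception-month cell a fixed-effect term equal to minus
    # the cell mean of the heat contribution, so the heat signal operates
    # through deviations from the local seasonal norm - exactly the
    # variation a fixed-effects regression identifies - and the cohort
    # rate stays at the baseline.  "none" sets the FE terms to zero, so
    # exposure shifts the level of risk across locations and seasons too.
    center: str = "cell"  # or "none"
    birthweight_mean: float = 3282.0
    birthweight_sd: float = 530.0
    birthweight_effects: dict[str, float] = field(default_factory=dict)

    def metric_spec(self) -> MetricSpec:
        return METRICS[self.metric]

    def validate(self) -> None:
        spec = self.metric_spec()
        valid = set(spec.regressor_names(include_omitted=True))
        bad = [k for k in self.band_effects if k not in valid]
        if bad:
            raise ValueError(
                f"band_effects names {bad} do not resolve against metric "
                f"{self.metric!r} regressors"
            )
        if self.link not in ("linear", "logistic"):
            raise ValueError("link must be 'linear' or 'logistic'")
        if self.center not in ("cell", "none"):
            raise ValueError("center must be 'cell' or 'none'")


@dataclass
class TruthRecord:
    """The exact DGP coefficients and per-birth latent probabilities."""

    baseline: float
    metric: str
    band_effects: dict[str, float]
    covariate_effects: dict[str, float]
    link: str
    clip_fraction: float
    latent_p: list[float]

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh)

    @classmethod
    def from_json(cls, path) -> "TruthRecord":
        with open(path) as fh:
            return cls(**json.load(fh))


def _sample_covariates(n: int, rng: np.random.Generator) -> pd.DataFrame:
    age_probs = np.array([0.08, 0.24, 0.30, 0.22, 0.12, 0.04])
    return pd.DataFrame(
        {
            "sex": rng.choice(["M", "F"], size=n, p=[0.512, 0.488]),
            "aboriginal": rng.binomial(1, 0.33, size=n),
            "first_pregnancy": rng.binomial(1, 0.40, size=n),
            "mother_age_band": rng.choice(AGE_BANDS, size=n, p=age_probs),
        }
    )


def gen_cohort(
    weather: pd.DataFrame,
    dgp: CohortDGP,
    seed: int,
    locations: list[str] | None = None,
) -> tuple[pd.DataFrame, TruthRecord]:
    """Generate a birth cohort whose preterm risk follows a known linear
    (or logistic) band-effect process over the supplied weather.

    Conception dates are sampled uniformly over ``dgp.conception_range``
    (sampling by conception avoids fixed-cohort bias); the weather must
    cover every conception date plus 273 days.  Returns the cohort table
    and the :class:`TruthRecord` of coefficients and latent probabilities.
    """
    dgp.validate()
    rng = np.random.default_rng([seed, 202])
    n = dgp.n_births
    if locations is None:
        locations = sorted(weather["location_id"].unique())
    if n == 0:
        cols = [
            "birth_id", "location_id", "birth_date", "conception_date",
            "gestational_weeks", "sex", "aboriginal", "first_pregnancy",
            "mother_age_band", "preterm", "birthweight_g",
        ]
        truth = TruthRecord(
            dgp.baseline_preterm_rate, dgp.metric, dict(dgp.band_effects),
            dict(dgp.covariate_effects), dgp.link, 0.0, [],
        )
        return pd.DataFrame(columns=cols), truth

    c0, c1 = dgp.conception_range
    span = (c1 - c0).days
    conc = np.array([c0 + timedelta(days=int(d)) for d in rng.integers(0, span + 1, size=n)])
    births = pd.DataFrame(
        {
            "birth_id": [f"b{i:06d}" for i in range(n)],
            "location_id": rng.choice(locations, size=n),
            "conception_date": conc,
        }
    )
    births = pd.concat([births, _sample_covariates(n, rng)], axis=1)

    spec = dgp.metric_spec()
    expo = build_exposures(births, weather, spec)
    heat = np.zeros(n, dtype=float)
    for name, eff in dgp.band_effects.items():
        heat += eff * expo[name].to_numpy()
    if dgp.center == "cell" and dgp.band_effects:
        cell = (
            births["location_id"].astype(str)
            + "|"
            + pd.to_datetime(births["conception_date"]).dt.month.astype(str)
        )
        heat = heat - pd.Series(heat).groupby(cell.to_numpy()).transform("mean").to_numpy()
    eta = dgp.baseline_preterm_rate + heat
    for cov, eff in dgp.covariate_effects.items():
        eta += eff * births[cov].astype(float).to_numpy()
    if dgp.link == "logistic":
        base = dgp.baseline_preterm_rate
        # shift on the logit scale so the null case keeps the baseline rate
        p = 1.0 / (1.0 + np.exp(-(np.log(base / (1 - base)) + (eta - base))))
        clip_frac = 0.0
    else:
        p = np.clip(eta, 0.0, 1.0)
        clip_frac = float(np.mean((eta < 0) | (eta > 1)))

    preterm = rng.binomial(1, p)
    weeks = np.where(
        preterm == 1,
        rng.integers(dgp.preterm_weeks[0], dgp.preterm_weeks[1] + 1, size=n),
        rng.integers(dgp.term_weeks[0], dgp.term_weeks[1] + 1, size=n),
    )
    births["gestational_weeks"] = weeks
    births["birth_date"] = [
        c + timedelta(weeks=int(w)) for c, w in zip(conc, weeks)
    ]
    births["preterm"] = preterm

    bw = dgp.birthweight_mean + rng.standard_normal(n) * dgp.birthweight_sd
    for name, eff in dgp.birthweight_effects.items():
        bw += eff * expo[name].to_numpy()
    births["birthweight_g"] = bw

    truth = TruthRecord(
        baseline=dgp.baseline_preterm_rate,
        metric=dgp.metric,
        band_effects=dict(dgp.band_effects),
        covariate_effects=dict(dgp.covariate_effects),
        link=dgp.link,
        clip_fraction=clip_frac,
        latent_p=p.tolist(),
    )
    return births, truth


COVARIATE_COLS = ("sex", "aboriginal", "first_pregnancy", "mother_age_band", "gestational_weeks")


def apply_exclusions(records: pd.DataFrame) -> tuple[pd.DataFrame, dict[str, int]]:
    """Drop births that cannot enter the analysis; report counts per reason.

    Rows with a missing location id are excluded first (reason
    ``ungeocodable``); of the remainder, rows missing any model covariate
    are excluded (reason ``missing_covariates``).  Row order is preserved.
    """
    if len(records) == 0:
        return records.copy(), {"ungeocodable": 0, "missing_covariates": 0}
    no_loc = records["location_id"].isna()
    cov_cols = [c for c in COVARIATE_COLS if c in records.columns]
    no_cov = records[cov_cols].isna().any(axis=1) & ~no_loc
    report = {
        "ungeocodable": int(no_loc.sum()),
        "missing_covariates": int(no_cov.sum()),
    }
    return records.loc[~(no_loc | no_cov)].copy(), report
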