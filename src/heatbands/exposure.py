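"""Per-birth, per-trimester exposure regressors for five heat metrics.

Gestation is dated from conception (birth date minus gestational weeks) and
split into trimesters of 12, 14 and 13 weeks.  Exposure is always computed
over the fixed 39-week (273-day) schedule from conception, including for
preterm births: truncating the third-trimester window at the actual birth
date would make exposure mechanically endogenous to the outcome.  A
``truncate_at_birth`` switch exists for sensitivity analysis only.

The five built-in metrics:

* ``benchmark`` - day counts of daily maximum temperature in 5-degree bands;
* ``trimester_average`` - mean daily maximum temperature per trimester;
* ``heatwave_count`` - number of heatwave events per trimester;
* ``max_and_min`` - benchmark plus daily-minimum bands;
* ``wet_bulb`` - daily-average and daily-maximum wet-bulb bands.

Band intervals are half-open [lower, upper): a printed band "20-24.99"
means [20, 25).  Omitted (reference) bands are materialised in the exposure
table, flagged via ``frame.attrs["omitted"]``, and excluded from design
matrices downstream, so that the per-trimester conservation identity
(counts sum to 84/98/91) stays testable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date, timedelta

import numpy as np
import pandas as pd

from . import thermo

__all__ = [
    "BandScheme",
    "MetricComponent",
    "MetricSpec",
    "METRICS",
    "TRIMESTER_OFFSETS",
    "TRIMESTER_LENGTHS",
    "GESTATION_DAYS",
    "conception_date",
    "trimester_windows",
    "count_band_days",
    "trimester_mean",
    "heatwave_count_in_window",
    "build_exposures",
]

# Trimester day offsets from conception: 12, 14 and 13 weeks.
TRIMESTER_OFFSETS = ((0, 84), (84, 182), (182, 273))
TRIMESTER_LENGTHS = (84, 98, 91)
GESTATION_DAYS = 273

PLAUSIBLE_WEEKS = (20, 45)


@dataclass(frozen=True)
class BandScheme:
    """An ordered set of half-open temperature bands covering the real line.

    ``breakpoints`` are the interior edges; labels are generated as
    ``lt{first}``, ``{a}_{b}`` ... ``ge{last}``.  ``omitted`` names the
    reference band left out of design matrices.
    """

    breakpoints: tuple[float, ...]
    omitted: str

    def __post_init__(self):
        bps = self.breakpoints
        if any(b2 <= b1 for b1, b2 in zip(bps, bps[1:])):
            raise ValueError("breakpoints must be strictly increasing")
        if self.omitted not in self.labels:
            raise ValueError(f"omitted band {self.omitted!r} not among {self.labels}")

    @property
    def labels(self) -> tuple[str, ...]:
        def fmt(x: float) -> str:
            return str(int(x)) if float(x).is_integer() else str(x)

        bps = self.breakpoints
        labs = [f"lt{fmt(bps[0])}"]
        labs += [f"{fmt(a)}_{fmt(b)}" for a, b in zip(bps, bps[1:])]
        labs.append(f"ge{fmt(bps[-1])}")
        return tuple(labs)

    def assign(self, values: np.ndarray) -> np.ndarray:
        """Band index of each value under the half-open [lower, upper) rule."""
        return np.searchsorted(np.asarray(self.breakpoints), values, side="right")


# Band schemes as used for the Northern Territory analysis.
MAX_BANDS = BandScheme((20, 25, 30, 35, 40), omitted="25_30")
MIN_BANDS = BandScheme((5, 10, 15, 20, 25), omitted="15_20")
WB_AVG_BANDS = BandScheme((10, 15, 20, 25), omitted="15_20")
WB_MAX_BANDS = BandScheme((10, 15, 20, 25, 30), omitted="20_25")


@dataclass(frozen=True)
class MetricComponent:
    """One term group of a metric: a banded field, a mean, or an event count."""

    kind: str  # {"banded", "mean", "heatwave"}
    field: str | None  # daily weather column; None for heatwave counts
    prefix: str
    scheme: BandScheme | None = None

    def __post_init__(self):
        if self.kind not in ("banded", "mean", "heatwave"):
            raise ValueError(f"unknown component kind {self.kind!r}")
        if self.kind == "banded" and self.scheme is None:
            raise ValueError("banded component requires a BandScheme")
        if self.kind in ("banded", "mean") and self.field is None:
            raise ValueError(f"{self.kind} component requires a daily field")


@dataclass(frozen=True)
class MetricSpec:
    """A named heat metric: one or more components applied per trimester."""

    name: str
    components: tuple[MetricComponent, ...]

    def regressor_names(self, include_omitted: bool = True) -> list[str]:
        names = []
        for k in (1, 2, 3):
            for comp in self.components:
                if comp.kind == "banded":
                    for lab in comp.scheme.labels:
                        if include_omitted or lab != comp.scheme.omitted:
                            names.append(f"{comp.prefix}_{lab}_t{k}")
                else:
                    names.append(f"{comp.prefix}_t{k}")
        return names

    def omitted_names(self) -> list[str]:
        return [
            f"{comp.prefix}_{comp.scheme.omitted}_t{k}"
            for k in (1, 2, 3)
            for comp in self.components
            if comp.kind == "banded"
        ]


METRICS: dict[str, MetricSpec] = {
    "benchmark": MetricSpec(
        "benchmark",
        (MetricComponent("banded", "tmax_c", "max", MAX_BANDS),),
    ),
    "trimester_average": MetricSpec(
        "trimester_average",
        (MetricComponent("mean", "tmax_c", "avg_tmax"),),
    ),
    "heatwave_count": MetricSpec(
        "heatwave_count",
        (MetricComponent("heatwave", None, "hw_count"),),
    ),
    "max_and_min": MetricSpec(
        "max_and_min",
        (
            MetricComponent("banded", "tmax_c", "max", MAX_BANDS),
            MetricComponent("banded", "tmin_c", "min", MIN_BANDS),
        ),
    ),
    "wet_bulb": MetricSpec(
        "wet_bulb",
        (
            MetricComponent("banded", "wb_mean_c", "wbavg", WB_AVG_BANDS),
            MetricComponent("banded", "wb_max_c", "wbmax", WB_MAX_BANDS),
        ),
    ),
}


def conception_date(birth_date: date, gestational_weeks: int) -> date:
    """Conception date = birth date minus 7 x gestational weeks days."""
    if not (PLAUSIBLE_WEEKS[0] <= gestational_weeks <= PLAUSIBLE_WEEKS[1]):
        import warnings

        warnings.warn(
            f"gestational_weeks={gestational_weeks} outside the plausible "
            f"range {PLAUSIBLE_WEEKS}",
            stacklevel=2,
        )
    return birth_date - timedelta(weeks=int(gestational_weeks))


@dataclass(frozen=True)
class GestationalWindows:
    """Half-open trimester day intervals from a conception date."""

    conception: date

    def window(self, k: int) -> tuple[date, date]:
        s, e = TRIMESTER_OFFSETS[k - 1]
        return (self.conception + timedelta(days=s), self.conception + timedelta(days=e))

    @property
    def w1(self):
        return self.window(1)

    @property
    def w2(self):
        return self.window(2)

    @property
    def w3(self):
        return self.window(3)


def trimester_windows(conception: date) -> GestationalWindows:
    return GestationalWindows(conception)


def _window_slice(series: pd.DataFrame, window: tuple[date, date]) -> pd.DataFrame:
    dates = pd.to_datetime(series["date"]).dt.date
    lo, hi = window
    if len(series) == 0 or dates.iloc[0] > lo or dates.iloc[-1] < hi - timedelta(days=1):
        raise ValueError(
            f"weather series does not cover [{lo}, {hi}); "
            f"available [{dates.iloc[0] if len(series) else None}, "
            f"{dates.iloc[-1] if len(series) else None}]"
        )
    mask = (dates >= lo) & (dates < hi)
    return series.loc[mask]


def count_band_days(
    series: pd.DataFrame, window: tuple[date, date], field: str, scheme: BandScheme
) -> dict[str, int]:
    """Day counts per band of ``field`` over a half-open date window."""
    sub = _window_slice(series, window)
    idx = scheme.assign(sub[field].to_numpy(dtype=float))
    counts = np.bincount(idx, minlength=len(scheme.labels))
    return dict(zip(scheme.labels, counts.tolist()))


def trimester_mean(series: pd.DataFrame, window: tuple[date, date], field: str) -> float:
    """Arithmetic mean of a daily field over a half-open date window."""
    sub = _window_slice(series, window)
    return float(sub[field].mean())


def heatwave_count_in_window(
    events: list[thermo.HeatwaveEvent], window: tuple[date, date]
) -> int:
    """Events attributed to the window by start date.

    An event straddling a trimester boundary counts once, in the trimester
    its first day falls in.
    """
    lo, hi = window
    return sum(1 for ev in events if lo <= ev.start_date < hi)


def _needs_column(spec: MetricSpec, col: str) -> bool:
    return any(c.field == col for c in spec.components)


def build_exposures(
    births: pd.DataFrame,
    weather: pd.DataFrame,
    spec: MetricSpec,
    heatwaves: list[thermo.HeatwaveEvent] | None = None,
    truncate_at_birth: bool = False,
) -> pd.DataFrame:
    """Exposure vectors for a birth cohort under one heat metric.

    Parameters
    ----------
    births : DataFrame
        Needs ``birth_id``, ``location_id`` and either ``conception_date``
        or (``birth_date``, ``gestational_weeks``).
    weather : DataFrame
        Daily weather covering every birth's 273-day schedule; must carry
        the daily fields the metric consumes (run
        :func:`heatbands.thermo.derive_daily_fields` for wet-bulb metrics).
    heatwaves : list of HeatwaveEvent, optional
        Pre-computed events for heatwave metrics; computed from the weather
        (with the default EHF baseline) when absent.
    truncate_at_birth : bool
        Sensitivity switch: zero out exposure days after the actual birth
        date.  Off by default (fixed 39-week schedule).

    Returns
    -------
    DataFrame indexed by ``birth_id`` with one column per regressor.
    ``frame.attrs["omitted"]`` lists reference-band columns to exclude from
    design matrices; ``frame.attrs["metric"]`` names the metric.
    """
    births = births.reset_index(drop=True)
    if "conception_date" not in births.columns:
        births["conception_date"] = [
            conception_date(bd, gw)
            for bd, gw in zip(
                pd.to_datetime(births["birth_date"]).dt.date, births["gestational_weeks"]
            )
        ]
    conc = pd.to_datetime(births["conception_date"])

    needed = [c.field for c in spec.components if c.field is not None]
    missing_cols = [c for c in needed if c not in weather.columns]
    if missing_cols:
        raise ValueError(
            f"weather lacks columns {missing_cols} required by metric {spec.name!r}"
        )

    needs_hw = any(c.kind == "heatwave" for c in spec.components)
    if needs_hw and heatwaves is None:
        w = weather
        if "ehf" not in w.columns:
            if "tmean_c" not in w.columns:
                w = thermo.derive_daily_fields(w)
            w = thermo.excess_heat_factor(w)
        heatwaves = thermo.detect_heatwaves(w)

    out_cols = spec.regressor_names(include_omitted=True)
    result = np.zeros((len(births), len(out_cols)), dtype=float)
    col_pos = {c: i for i, c in enumerate(out_cols)}

    uncovered: list = []
    for loc, grp in births.groupby("location_id", sort=False):
        wloc = weather.loc[weather["location_id"] == loc]
        if len(wloc) == 0:
            uncovered.extend(grp["birth_id"].tolist())
            continue
        wdates = pd.to_datetime(wloc["date"]).to_numpy(dtype="datetime64[D]")
        day0 = wdates[0]
        n_days = len(wdates)
        conc_off = (
            conc.loc[grp.index].to_numpy(dtype="datetime64[D]") - day0
        ).astype(int)
        bad = (conc_off < 0) | (conc_off + GESTATION_DAYS > n_days)
        if bad.any():
            uncovered.extend(grp["birth_id"].to_numpy()[bad].tolist())
        ok = ~bad
        rows = grp.index.to_numpy()[ok]
        off = conc_off[ok]

        if truncate_at_birth and "birth_date" in births.columns:
            bdates = pd.to_datetime(births.loc[grp.index, "birth_date"]).to_numpy(
                dtype="datetime64[D]"
            )
            stop = (bdates - day0).astype(int)[ok]  # exclusive day offset
        else:
            stop = None

        for comp in spec.components:
            if comp.kind == "banded":
                vals = wloc[comp.field].to_numpy(dtype=float)
                idx = comp.scheme.assign(vals)
                nb = len(comp.scheme.labels)
                # prefix sums of band indicators: csum[b, d] = #days < d in band b
                ind = np.zeros((nb, n_days + 1))
                for b in range(nb):
                    ind[b, 1:] = np.cumsum(idx == b)
                for k, (s, e) in enumerate(TRIMESTER_OFFSETS, start=1):
                    lo = off + s
                    hi = off + e
                    if stop is not None:
                        hi = np.minimum(hi, np.maximum(stop, lo))
                    for b, lab in enumerate(comp.scheme.labels):
                        cnt = ind[b, hi] - ind[b, lo]
                        result[rows, col_pos[f"{comp.prefix}_{lab}_t{k}"]] = cnt
            elif comp.kind == "mean":
                vals = wloc[comp.field].to_numpy(dtype=float)
                csum = np.concatenate([[0.0], np.cumsum(vals)])
                for k, (s, e) in enumerate(TRIMESTER_OFFSETS, start=1):
                    lo = off + s
                    hi = off + e
                    if stop is not None:
                        hi = np.minimum(hi, np.maximum(stop, lo + 1))
                    mean = (csum[hi] - csum[lo]) / np.maximum(hi - lo, 1)
                    result[rows, col_pos[f"{comp.prefix}_t{k}"]] = mean
            else:  # heatwave
                starts = np.sort(
                    np.array(
                        [
                            (np.datetime64(ev.start_date, "D") - day0).astype(int)
                            for ev in heatwaves
                            if ev.location_id == loc
                        ],
                        dtype=int,
                    )
                )
                for k, (s, e) in enumerate(TRIMESTER_OFFSETS, start=1):
                    lo = off + s
                    hi = off + e
                    if stop is not None:
                        hi = np.minimum(hi, np.maximum(stop, lo))
                    cnt = np.searchsorted(starts, hi, side="left") - np.searchsorted(
                        starts, lo, side="left"
                    )
                    result[rows, col_pos[f"{comp.prefix}_t{k}"]] = cnt

    if uncovered:
        raise ValueError(
            f"weather does not cover the 273-day schedule for "
            f"{len(uncovered)} births: {uncovered[:10]}{'...' if len(uncovered) > 10 else ''}"
        )

    frame = pd.DataFrame(result, columns=out_cols, index=pd.Index(births["birth_id"], name="birth_id"))
    frame.attrs["metric"] = spec.name
    frame.attrs["omitted"] = spec.omitted_names()
    return frame
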