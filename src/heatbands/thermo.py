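"""Derived thermal quantities from raw daily weather.

Inputs are per-location daily series of maximum temperature, minimum
temperature and relative humidity.  From these we derive the daily mean
temperature, wet-bulb temperatures via Stull's single-equation empirical
approximation, the Excess Heat Factor (EHF) used operationally by the
Australian Bureau of Meteorology, and heatwave events (three or more
consecutive days with a positive EHF).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from datetime import date

import numpy as np
import pandas as pd

__all__ = [
    "wet_bulb_stull",
    "derive_daily_fields",
    "excess_heat_factor",
    "detect_heatwaves",
    "HeatwaveEvent",
    "validate_weather",
]

# Approximate validity envelope of the Stull (2011) fit: the regression was
# trained on temperatures between about -20 and 50 degC and RH of 5-99 %.
STULL_T_RANGE = (-20.0, 50.0)
STULL_RH_MIN = 5.0

WEATHER_BASE_COLS = ["location_id", "date", "tmax_c", "tmin_c", "rh_pct"]


def wet_bulb_stull(t, rh):
    """Wet-bulb temperature (degC) from dry-bulb temperature and RH.

    Uses Stull's one-line empirical inverse of the psychrometric
    relationship, accurate to a few tenths of a degree over its fitted
    range.  Accepts scalars or numpy arrays.

    Parameters
    ----------
    t : float or array
        Air temperature in degC.
    rh : float or array
        Relative humidity in percent, within [0, 100].
    """
    t = np.asarray(t, dtype=float)
    rh = np.asarray(rh, dtype=float)
    if np.any(rh < 0) or np.any(rh > 100):
        raise ValueError("relative humidity must be within [0, 100] percent")
    if np.any(t < STULL_T_RANGE[0]) or np.any(t > STULL_T_RANGE[1]) or np.any(
        rh < STULL_RH_MIN
    ):
        warnings.warn(
            "input outside the fitted validity envelope of Stull's wet-bulb "
            f"approximation (T in {STULL_T_RANGE} degC, RH >= {STULL_RH_MIN} %)",
            stacklevel=2,
        )
    tw = (
        t * np.arctan(0.151977 * np.sqrt(rh + 8.313659))
        + np.arctan(t + rh)
        - np.arctan(rh - 1.676331)
        + 0.00391838 * rh ** 1.5 * np.arctan(0.023101 * rh)
        - 4.686035
    )
    if tw.ndim == 0:
        return float(tw)
    return tw


def validate_weather(weather: pd.DataFrame) -> None:
    """Check the daily-weather contract: required columns, gap-free
    consecutive dates per location, tmin <= tmax, RH within [0, 100]."""
    missing = [c for c in WEATHER_BASE_COLS if c not in weather.columns]
    if missing:
        raise ValueError(f"weather table missing columns: {missing}")
    if len(weather) == 0:
        return
    if (weather["tmin_c"] > weather["tmax_c"]).any():
        bad = weather.loc[weather["tmin_c"] > weather["tmax_c"], "date"].iloc[0]
        raise ValueError(f"tmin exceeds tmax (first offending date: {bad})")
    if (weather["rh_pct"] < 0).any() or (weather["rh_pct"] > 100).any():
        raise ValueError("relative humidity outside [0, 100]")
    dates = pd.to_datetime(weather["date"])
    for loc, grp in dates.groupby(weather["location_id"], sort=False):
        diffs = grp.diff().dropna()
        if (diffs != pd.Timedelta(days=1)).any():
            raise ValueError(f"dates for location {loc!r} are not gap-free daily")


def derive_daily_fields(weather: pd.DataFrame) -> pd.DataFrame:
    """Append derived daily fields to a weather table.

    Adds ``tmean_c`` = (tmax + tmin) / 2, ``wb_max_c`` = Stull(tmax, rh) and
    ``wb_mean_c`` = Stull(tmean, rh).  The daily-mean wet bulb is computed
    from the daily-mean air temperature because the generator provides a
    single RH value per day; only monotone band membership is consumed
    downstream.
    """
    validate_weather(weather)
    out = weather.copy()
    out["tmean_c"] = (out["tmax_c"] + out["tmin_c"]) / 2.0
    with warnings.catch_warnings():
        # envelope warnings would repeat once per call on cold-climate input
        warnings.simplefilter("ignore")
        out["wb_max_c"] = wet_bulb_stull(out["tmax_c"].to_numpy(), out["rh_pct"].to_numpy())
        out["wb_mean_c"] = wet_bulb_stull(out["tmean_c"].to_numpy(), out["rh_pct"].to_numpy())
    return out


def _ehf_one_location(tmean: np.ndarray, long_term_mean: float) -> np.ndarray:
    """EHF for one gap-free series; NaN where history is insufficient.

    For day d (0-based), T3 is the mean of tmean over {d-2, d-1, d} and T30
    the mean over the 30 days ending at d-3.  EHI_sig = T3 - long_term_mean,
    EHI_accl = T3 - T30, EHF = EHI_sig * max(1, EHI_accl).  The first scored
    day is therefore index 32.
    """
    n = len(tmean)
    ehf = np.full(n, np.nan)
    if n < 33:
        return ehf
    csum = np.concatenate([[0.0], np.cumsum(tmean)])
    d = np.arange(32, n)
    t3 = (csum[d + 1] - csum[d - 2]) / 3.0
    t30 = (csum[d - 2] - csum[d - 32]) / 30.0
    ehi_sig = t3 - long_term_mean
    ehi_accl = t3 - t30
    ehf[32:] = ehi_sig * np.maximum(1.0, ehi_accl)
    return ehf


def excess_heat_factor(
    weather: pd.DataFrame,
    long_term_mean: dict | float | None = None,
    baseline: str = "mean",
) -> pd.DataFrame:
    """Score each day's Excess Heat Factor, per location.

    The significance term compares the trailing 3-day mean temperature with
    a long-term location baseline; the acclimatisation term compares it with
    the mean of the preceding 30 days (ending 3 days earlier).  Days with
    fewer than 32 days of history are left unscored (NaN).

    Parameters
    ----------
    weather : DataFrame
        Must carry ``tmean_c`` (see :func:`derive_daily_fields`).
    long_term_mean : mapping location_id -> degC, scalar, or None
        Baseline per location.  If None it is computed from the series
        itself according to ``baseline``.
    baseline : {"mean", "p95"}
        With no explicit baseline, use the long-term mean of the daily mean
        temperature (default, following the verbal definition used here) or
        the 95th percentile (the Nairn-Fawcett operational variant).
    """
    if "tmean_c" not in weather.columns:
        raise ValueError("weather must carry tmean_c; run derive_daily_fields first")
    if baseline not in ("mean", "p95"):
        raise ValueError("baseline must be 'mean' or 'p95'")
    out = weather.copy()
    out["ehf"] = np.nan
    for loc, grp in out.groupby("location_id", sort=False):
        tm = grp["tmean_c"].to_numpy(dtype=float)
        if isinstance(long_term_mean, dict):
            base = float(long_term_mean[loc])
        elif long_term_mean is not None:
            base = float(long_term_mean)
        elif baseline == "p95":
            base = float(np.percentile(tm, 95))
        else:
            base = float(tm.mean())
        if len(tm) < 33:
            warnings.warn(
                f"location {loc!r}: series shorter than the 33-day warm-up; "
                "all days unscored",
                stacklevel=2,
            )
        out.loc[grp.index, "ehf"] = _ehf_one_location(tm, base)
    return out


@dataclass(frozen=True)
class HeatwaveEvent:
    """A maximal run of >= 3 consecutive days with positive EHF."""

    location_id: str
    start_date: date
    end_date: date  # inclusive

    @property
    def duration(self) -> int:
        return (self.end_date - self.start_date).days + 1


def detect_heatwaves(weather: pd.DataFrame, min_days: int = 3) -> list[HeatwaveEvent]:
    """Find heatwave events: maximal runs of consecutive days with EHF > 0
    and length >= ``min_days``, per location, ordered by start date.

    Unscored (NaN) days never count as positive.
    """
    if "ehf" not in weather.columns:
        raise ValueError("weather must carry an 'ehf' column; run excess_heat_factor")
    events: list[HeatwaveEvent] = []
    for loc, grp in weather.groupby("location_id", sort=False):
        pos = (grp["ehf"].to_numpy(dtype=float) > 0).astype(int)
        dates = pd.to_datetime(grp["date"]).dt.date.to_numpy()
        # run boundaries of the 0/1 indicator
        padded = np.concatenate([[0], pos, [0]])
        starts = np.flatnonzero(np.diff(padded) == 1)
        ends = np.flatnonzero(np.diff(padded) == -1)  # exclusive
        for s, e in zip(starts, ends):
            if e - s >= min_days:
                events.append(HeatwaveEvent(loc, dates[s], dates[e - 1]))
    events.sort(key=lambda ev: (str(ev.location_id), ev.start_date))
    return events


def heatwaves_to_frame(events: list[HeatwaveEvent]) -> pd.DataFrame:
    """Events as a CSV-ready table: location_id,start_date,end_date,duration."""
    return pd.DataFrame(
        [
            {
                "location_id": ev.location_id,
                "start_date": ev.start_date.isoformat(),
                "end_date": ev.end_date.isoformat(),
                "duration": ev.duration,
            }
            for ev in events
        ],
        columns=["location_id", "start_date", "end_date", "duration"],
    )
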