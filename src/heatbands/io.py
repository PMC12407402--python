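"""CSV dialects for the pipeline's tabular artifacts.

All dates are ISO-8601, temperatures degC, humidity percent; band day
intervals are half-open.  Weather: ``location_id,date,tmax_c,tmin_c,rh_pct``
(+ derived columns when present).  Births:
``birth_id,location_id,birth_date,gestational_weeks,sex,aboriginal,
first_pregnancy,mother_age_band,preterm,birthweight_g``.
"""

from __future__ import annotations

import pandas as pd

WEATHER_COLS = ["location_id", "date", "tmax_c", "tmin_c", "rh_pct"]
BIRTH_COLS = [
    "birth_id", "location_id", "birth_date", "gestational_weeks", "sex",
    "aboriginal", "first_pregnancy", "mother_age_band", "preterm", "birthweight_g",
]


def write_weather_csv(weather: pd.DataFrame, path) -> None:
    out = weather.copy()
    out["date"] = pd.to_datetime(out["date"]).dt.date
    out.to_csv(path, index=False)


def read_weather_csv(path) -> pd.DataFrame:
    w = pd.read_csv(path, dtype={"location_id": str})
    missing = [c for c in WEATHER_COLS if c not in w.columns]
    if missing:
        raise ValueError(f"weather CSV missing columns {missing}")
    w["date"] = pd.to_datetime(w["date"])
    return w


def write_births_csv(births: pd.DataFrame, path) -> None:
    out = births.copy()
    for col in ("birth_date", "conception_date"):
        if col in out.columns:
            out[col] = pd.to_datetime(out[col]).dt.date
    out.to_csv(path, index=False)


def read_births_csv(path) -> pd.DataFrame:
    b = pd.read_csv(path, dtype={"location_id": str, "birth_id": str})
    missing = [c for c in BIRTH_COLS if c not in b.columns and c != "birthweight_g"]
    if missing:
        raise ValueError(f"births CSV missing columns {missing}")
    b["birth_date"] = pd.to_datetime(b["birth_date"])
    if "conception_date" in b.columns:
        b["conception_date"] = pd.to_datetime(b["conception_date"])
    return b


def write_locations_csv(points, path) -> None:
    pd.DataFrame(
        [{"location_id": p.location_id, "lat": p.lat, "lon": p.lon} for p in points]
    ).to_csv(path, index=False)


def read_locations_csv(path):
    from .geocluster import GeoPoint

    df = pd.read_csv(path, dtype={"location_id": str})
    return [GeoPoint(r.location_id, float(r.lat), float(r.lon)) for r in df.itertuples()]
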