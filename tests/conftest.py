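"""Shared fixtures: a small single-location weather series for unit tests
and a session-scoped mid-size study (100 locations, 5 years of weather,
10,000 births) reused by the simulation-based tests."""

from __future__ import annotations

from datetime import date

import numpy as np
import pandas as pd
import pytest

import heatbands as hb
from heatbands import fe_model
from heatbands import synthetic_data as sd

WEATHER_YEARS = (date(2000, 1, 1), date(2004, 12, 31))
CONCEPTION_YEARS = (date(2001, 1, 1), date(2003, 12, 31))


@pytest.fixture(scope="session")
def tropical_weather():
    """One tropical location, 4 years, derived fields attached."""
    w = sd.gen_weather(sd.TROPICAL, ["trop00"], (date(2000, 1, 1), date(2003, 12, 31)), seed=1)
    return hb.derive_daily_fields(w)


@pytest.fixture(scope="session")
def study():
    """The synthetic study: locations, weather, clusters, and a null cohort.

    The geography mirrors the scale of the population the pipeline is
    meant for: ~100 scattered locations collapsing to several dozen
    50-mile clusters, so cluster-robust inference has a healthy cluster
    count.
    """
    pts, zones = sd.default_locations(seed=0)
    frames = []
    for zone, params in sd.ZONES.items():
        locs = [p for p in pts if zones[p.location_id] == zone]
        frames.append(sd.gen_weather(params, locs, WEATHER_YEARS, seed=7))
    weather = hb.derive_daily_fields(pd.concat(frames, ignore_index=True))
    weather = hb.excess_heat_factor(weather)
    assignment = hb.cluster_max_diameter(pts)
    heatwaves = hb.detect_heatwaves(weather)
    return {
        "points": pts,
        "zones": zones,
        "weather": weather,
        "assignment": assignment,
        "heatwaves": heatwaves,
    }


def _solvers_for(births, study, metrics):
    solvers = {}
    exposures = {}
    for m in metrics:
        expo = hb.build_exposures(
            births, study["weather"], hb.METRICS[m], heatwaves=study["heatwaves"]
        )
        exposures[m] = expo
        heat_cols = [c for c in expo.columns if c not in expo.attrs["omitted"]]
        design = fe_model.build_design(
            births,
            expo,
            fe_model.ModelSpec(heat_terms={m: heat_cols}),
            cluster_map=study["assignment"].assignment,
        )
        solvers[m] = fe_model.WithinSolver(design)
    return exposures, solvers


@pytest.fixture(scope="session")
def null_cohort(study):
    """10,000 births with no heat effect (latent rate 0.10 everywhere)."""
    dgp = sd.CohortDGP(n_births=10_000, conception_range=CONCEPTION_YEARS)
    births, truth = sd.gen_cohort(study["weather"], dgp, seed=3)
    exposures, solvers = _solvers_for(births, study, list(hb.METRICS))
    return {"births": births, "truth": truth, "exposures": exposures, "solvers": solvers}


@pytest.fixture(scope="session")
def planted_cohort(study):
    """10,000 births whose preterm risk follows the reference max-and-min
    band-effect profile (known ground truth for identification checks)."""
    dgp = sd.CohortDGP(
        n_births=10_000,
        conception_range=CONCEPTION_YEARS,
        band_effects=dict(sd.MODERATE_BAND_EFFECTS),
        covariate_effects=dict(sd.DEFAULT_COVARIATE_EFFECTS),
    )
    births, truth = sd.gen_cohort(study["weather"], dgp, seed=3)
    exposures, solvers = _solvers_for(births, study, list(hb.METRICS))
    return {"births": births, "truth": truth, "exposures": exposures, "solvers": solvers}
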