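"""End-to-end orchestration: simulate -> derive -> cluster -> exposures ->
fit (one model per metric) -> select -> predict.

A single seed in the configuration is expanded into stage-specific
substreams with stable labels, so changing one stage's draws never
perturbs another's.  Every run serialises its configuration into the
output directory for provenance; outputs are deterministic given the seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from datetime import date
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import counterfactual, fe_model, io, metric_selection, synthetic_data, thermo
from .exposure import METRICS, build_exposures
from .geocluster import cluster_max_diameter

__all__ = ["PipelineConfig", "run_pipeline"]

logger = logging.getLogger(__name__)

_STAGE_SALT = {"weather": 11, "cohort": 23, "scenario": 37}


def _stage_seed(seed: int, stage: str) -> int:
    return (seed * 1_000_003 + _STAGE_SALT[stage]) % (2**31 - 1)


@dataclass
class PipelineConfig:
    """Validated configuration for a full pipeline run."""

    seed: int = 0
    n_tropical_locations: int = 50
    n_arid_locations: int = 50
    weather_start: date = date(2000, 1, 1)
    weather_end: date = date(2004, 12, 31)
    conception_start: date = date(2001, 1, 1)
    conception_end: date = date(2003, 12, 31)
    n_births: int = 3000
    baseline_preterm_rate: float = 0.10
    dgp_metric: str = "max_and_min"
    band_effects: dict = field(default_factory=dict)
    covariate_effects: dict = field(default_factory=dict)
    metrics: tuple = ("benchmark", "trimester_average", "heatwave_count", "max_and_min", "wet_bulb")
    selection_alpha: float = 0.05
    cluster_max_miles: float = 50.0
    run_counterfactual: bool = True
    strata: dict = field(default_factory=dict)  # e.g. {"aboriginal": 1}

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("weather_start", "weather_end", "conception_start", "conception_end"):
            if key in raw and isinstance(raw[key], str):
                raw[key] = date.fromisoformat(raw[key])
        if "metrics" in raw:
            raw["metrics"] = tuple(raw["metrics"])
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        unknown = [m for m in self.metrics if m not in METRICS]
        if unknown:
            raise ValueError(f"unknown metrics: {unknown}")
        if self.dgp_metric not in METRICS:
            raise ValueError(f"unknown DGP metric {self.dgp_metric!r}")
        if not (self.weather_start <= self.conception_start <= self.conception_end <= self.weather_end):
            raise ValueError("conception range must lie inside the weather range")
        if not 0 < self.selection_alpha <= 1:
            raise ValueError("selection_alpha must lie in (0, 1]")

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        for key in ("weather_start", "weather_end", "conception_start", "conception_end"):
            d[key] = d[key].isoformat()
        d["metrics"] = list(d["metrics"])
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)


def simulate_stage(cfg: PipelineConfig):
    """Generate locations, weather (with derived fields) and the cohort."""
    points, zones = synthetic_data.default_locations(
        cfg.n_tropical_locations, cfg.n_arid_locations, seed=cfg.seed
    )
    wseed = _stage_seed(cfg.seed, "weather")
    frames = []
    for zone_label, params in synthetic_data.ZONES.items():
        locs = [p for p in points if zones[p.location_id] == zone_label]
        if locs:
            frames.append(
                synthetic_data.gen_weather(
                    params, locs, (cfg.weather_start, cfg.weather_end), wseed
                )
            )
    weather = pd.concat(frames, ignore_index=True)
    weather = thermo.derive_daily_fields(weather)
    weather = thermo.excess_heat_factor(weather)

    dgp = synthetic_data.CohortDGP(
        baseline_preterm_rate=cfg.baseline_preterm_rate,
        metric=cfg.dgp_metric,
        band_effects=dict(cfg.band_effects),
        covariate_effects=dict(cfg.covariate_effects),
        n_births=cfg.n_births,
        conception_range=(cfg.conception_start, cfg.conception_end),
    )
    births, truth = synthetic_data.gen_cohort(weather, dgp, _stage_seed(cfg.seed, "cohort"))
    births["zone"] = births["location_id"].map(zones)
    return points, zones, weather, births, truth


def run_pipeline(cfg: PipelineConfig, out_dir) -> Path:
    """Run all stages, writing CSV/JSON artifacts to ``out_dir``."""
    cfg.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg.to_yaml(out / "config.yaml")

    logger.info("stage: simulate")
    points, zones, weather, births, truth = simulate_stage(cfg)
    io.write_weather_csv(weather, out / "weather.csv")
    truth.to_json(out / "truth.json")

    logger.info("stage: exclusions")
    births, excl = synthetic_data.apply_exclusions(births)
    (out / "exclusions.json").write_text(json.dumps(excl))

    if cfg.strata:
        for col, val in cfg.strata.items():
            n_before = len(births)
            births = births[births[col] == val]
            logger.info("stratify %s=%r: %d -> %d rows", col, val, n_before, len(births))
    io.write_births_csv(births, out / "births.csv")

    logger.info("stage: cluster")
    assignment = cluster_max_diameter(points, cfg.cluster_max_miles)
    assignment.to_frame().to_csv(out / "clusters.csv", index=False)

    logger.info("stage: exposures + fit")
    heatwaves = thermo.detect_heatwaves(weather)
    thermo.heatwaves_to_frame(heatwaves).to_csv(out / "heatwaves.csv", index=False)

    fits = {}
    exposures = {}
    for name in cfg.metrics:
        spec = METRICS[name]
        expo = build_exposures(births, weather, spec, heatwaves=heatwaves)
        exposures[name] = expo
        heat_cols = [c for c in expo.columns if c not in expo.attrs["omitted"]]
        design = fe_model.build_design(
            births, expo, fe_model.ModelSpec(heat_terms={name: heat_cols}),
            cluster_map=assignment.assignment,
        )
        fit = fe_model.fit_fe_model(design)
        fits[name] = fit
        fit.coef_table().to_csv(out / f"coefs_{name}.csv")
        logger.info("fitted %s: k=%d, within adj R2=%.4f, AIC=%.1f", name, fit.k, fit.within_adj_r2, fit.aic)

    logger.info("stage: select")
    report = metric_selection.rank_and_select(fits, cfg.selection_alpha)
    report.to_csv(out / "selection.csv")
    (out / "selection.json").write_text(
        json.dumps({"preferred": report.preferred, "rationale": report.rationale})
    )

    if cfg.run_counterfactual:
        logger.info("stage: predict")
        profile = counterfactual.day_of_year_climatology(weather)
        preferred = report.preferred
        scen = {
            s: counterfactual.scenario_exposure(profile, s, METRICS[preferred])
            for s in ("hottest9", "coolest9")
        }
        pred = counterfactual.predict_rates(
            fits[preferred], exposures[preferred], scen, births
        )
        pred.to_frame().to_csv(out / "predictions.csv", index=False)

    logger.info("pipeline complete: %s", out)
    return out
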