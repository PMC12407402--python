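"""Climatology construction and hottest-vs-coolest scenario predictions."""

from datetime import date

import numpy as np
import pandas as pd
import pytest

import heatbands as hb
from heatbands import counterfactual as cf
from heatbands import synthetic_data as sd
from heatbands.exposure import METRICS, TRIMESTER_LENGTHS


def _weather_years(tmax_fn, years=(2001,), loc="L1", rh=60.0):
    frames = []
    for y in years:
        dates = pd.date_range(date(y, 1, 1), date(y, 12, 31), freq="D")
        doy = dates.dayofyear.to_numpy()
        tmax = tmax_fn(doy)
        frames.append(
            pd.DataFrame(
                {
                    "location_id": loc,
                    "date": dates,
                    "tmax_c": tmax,
                    "tmin_c": tmax - 8.0,
                    "rh_pct": rh,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


class TestClimatology:
    def test_single_noise_free_year_reproduced_exactly(self):
        w = _weather_years(lambda d: 30 + 3 * np.cos(2 * np.pi * (d - 1) / 365))
        prof = cf.day_of_year_climatology(w)
        merged = w.copy()
        merged["month"] = pd.to_datetime(merged["date"]).dt.month
        merged["day"] = pd.to_datetime(merged["date"]).dt.day
        joined = merged.merge(prof, on=["location_id", "month", "day"], suffixes=("", "_p"))
        np.testing.assert_allclose(joined["tmax_c"], joined["tmax_c_p"])

    def test_two_offset_years_give_midpoint(self):
        w1 = _weather_years(lambda d: np.full(len(d), 30.0), years=(2001,))
        w2 = _weather_years(lambda d: np.full(len(d), 32.0), years=(2002,))
        prof = cf.day_of_year_climatology(pd.concat([w1, w2], ignore_index=True))
        assert np.allclose(prof["tmax_c"], 31.0)

    def test_incomplete_year_excluded_with_warning(self):
        w = _weather_years(lambda d: np.full(len(d), 30.0), years=(2001,))
        partial = _weather_years(lambda d: np.full(len(d), 40.0), years=(2002,)).head(100)
        with pytest.warns(UserWarning, match="incomplete"):
            prof = cf.day_of_year_climatology(pd.concat([w, partial], ignore_index=True))
        assert np.allclose(prof["tmax_c"], 30.0)

    def test_stationary_noise_gives_flat_profile(self):
        rng = np.random.default_rng(3)
        frames = []
        for y in (2001, 2002, 2003, 2004):
            dates = pd.date_range(date(y, 1, 1), date(y, 12, 31), freq="D")
            tmax = 30.0 + rng.standard_normal(len(dates))
            frames.append(
                pd.DataFrame(
                    {"location_id": "L1", "date": dates, "tmax_c": tmax,
                     "tmin_c": tmax - 8, "rh_pct": 60.0}
                )
            )
        prof = cf.day_of_year_climatology(pd.concat(frames, ignore_index=True))
        assert prof["tmax_c"].std() < 3 * 1.0 / np.sqrt(4)

    def test_leap_day_filled(self):
        w = _weather_years(lambda d: np.full(len(d), 30.0), years=(2001,))
        prof = cf.day_of_year_climatology(w)
        assert len(prof) == 366
        feb29 = prof[(prof["month"] == 2) & (prof["day"] == 29)]
        assert len(feb29) == 1


class TestScenarioExposure:
    def test_flat_climatology_makes_scenarios_identical(self):
        w = _weather_years(lambda d: np.full(len(d), 30.0), years=(2001,))
        prof = cf.day_of_year_climatology(w)
        hot = cf.scenario_exposure(prof, "hottest9", METRICS["benchmark"])
        cool = cf.scenario_exposure(prof, "coolest9", METRICS["benchmark"])
        pd.testing.assert_frame_equal(hot, cool)

    def test_tropical_profile_hot_scenario_dominates_high_bands(self, study):
        trop = study["weather"][study["weather"]["location_id"] == "trop00"]
        prof = cf.day_of_year_climatology(trop)
        spec = METRICS["benchmark"]
        hot = cf.scenario_exposure(prof, "hottest9", spec)
        cool = cf.scenario_exposure(prof, "coolest9", spec)
        hot_days = sum(hot.loc["trop00", f"max_{b}_t{k}"] for b in ("30_35", "35_40", "ge40") for k in (1, 2, 3))
        cool_days = sum(cool.loc["trop00", f"max_{b}_t{k}"] for b in ("30_35", "35_40", "ge40") for k in (1, 2, 3))
        assert hot_days >= cool_days

    def test_conservation_holds_for_scenario_vectors(self, study):
        prof = cf.day_of_year_climatology(study["weather"])
        expo = cf.scenario_exposure(prof, "hottest9", METRICS["max_and_min"])
        for prefix in ("max", "min"):
            for k, length in zip((1, 2, 3), TRIMESTER_LENGTHS):
                cols = [c for c in expo.columns if c.startswith(f"{prefix}_") and c.endswith(f"_t{k}")]
                assert (expo[cols].sum(axis=1) == length).all()

    def test_unknown_scenario_rejected(self, study):
        prof = cf.day_of_year_climatology(
            study["weather"][study["weather"]["location_id"] == "trop00"]
        )
        with pytest.raises(ValueError, match="scenario"):
            cf.scenario_exposure(prof, "mild9", METRICS["benchmark"])


@pytest.fixture(scope="module")
def scenario_pair(study):
    prof = cf.day_of_year_climatology(study["weather"])
    spec = METRICS["max_and_min"]
    return {
        s: cf.scenario_exposure(prof, s, spec) for s in ("hottest9", "coolest9")
    }


class TestPredictRates:
    def test_zero_heat_coefficients_reproduce_observed_rate(self, null_cohort, scenario_pair):
        fit = null_cohort["solvers"]["max_and_min"].fit()
        zero = fit.params.copy()
        zero[:] = 0.0
        fit.params = zero
        pred = cf.predict_rates(
            fit, null_cohort["exposures"]["max_and_min"], scenario_pair, null_cohort["births"]
        )
        ybar = null_cohort["births"]["preterm"].mean()
        assert pred.rates["hottest9"] == pytest.approx(ybar)
        assert pred.rates["coolest9"] == pytest.approx(ybar)
        assert pred.difference == 0.0

    def test_difference_is_exactly_hot_minus_cool(self, planted_cohort, scenario_pair):
        fit = planted_cohort["solvers"]["max_and_min"].fit()
        pred = cf.predict_rates(
            fit, planted_cohort["exposures"]["max_and_min"], scenario_pair, planted_cohort["births"]
        )
        # clipping aside, difference equals the rate gap
        raw_gap = pred.rates["hottest9"] - pred.rates["coolest9"]
        if not any(pred.clipped.values()):
            assert pred.difference == pytest.approx(raw_gap)

    def test_ci_nesting(self, planted_cohort, scenario_pair):
        fit = planted_cohort["solvers"]["max_and_min"].fit()
        pred = cf.predict_rates(
            fit, planted_cohort["exposures"]["max_and_min"], scenario_pair, planted_cohort["births"]
        )
        for qty in ("hottest9", "coolest9", "difference"):
            l68, h68 = pred.ci[qty][0.68]
            l80, h80 = pred.ci[qty][0.80]
            l95, h95 = pred.ci[qty][0.95]
            assert l95 <= l80 <= l68 <= h68 <= h80 <= h95

    def test_difference_independent_of_baseline_level(self, planted_cohort, scenario_pair):
        # the fixed-effect/covariate component cancels: shifting the
        # observed mean outcome leaves the scenario difference unchanged
        sol = planted_cohort["solvers"]["max_and_min"]
        fit1 = sol.fit()
        pred1 = cf.predict_rates(
            fit1, planted_cohort["exposures"]["max_and_min"], scenario_pair, planted_cohort["births"]
        )
        fit2 = sol.fit()
        fit2.y_mean = fit1.y_mean + 0.37
        pred2 = cf.predict_rates(
            fit2, planted_cohort["exposures"]["max_and_min"], scenario_pair, planted_cohort["births"]
        )
        assert pred2.difference == pytest.approx(pred1.difference)

    def test_delta_and_simulation_cis_agree(self, planted_cohort, scenario_pair):
        fit = planted_cohort["solvers"]["max_and_min"].fit()
        args = (fit, planted_cohort["exposures"]["max_and_min"], scenario_pair, planted_cohort["births"])
        delta = cf.predict_rates(*args, method="delta")
        sim = cf.predict_rates(*args, method="simulation", n_draws=10_000, seed=5)
        for qty in ("hottest9", "coolest9", "difference"):
            hw_d = (delta.ci[qty][0.95][1] - delta.ci[qty][0.95][0]) / 2
            hw_s = (sim.ci[qty][0.95][1] - sim.ci[qty][0.95][0]) / 2
            assert hw_s == pytest.approx(hw_d, rel=0.10)

    def test_planted_truth_difference_recovered(self, planted_cohort, scenario_pair):
        """The estimated hottest-coolest gap matches the analytic truth
        computed by applying the DGP coefficients to the scenario contrast."""
        births = planted_cohort["births"]
        expo = planted_cohort["exposures"]["max_and_min"]
        truth_b = sd.MODERATE_BAND_EFFECTS
        cols = list(truth_b)
        xs_hot = scenario_pair["hottest9"].loc[births["location_id"], cols].to_numpy()
        xs_cool = scenario_pair["coolest9"].loc[births["location_id"], cols].to_numpy()
        tv = np.array([truth_b[c] for c in cols])
        true_diff = float(((xs_hot - xs_cool).mean(axis=0) @ tv))

        fit = planted_cohort["solvers"]["max_and_min"].fit()
        pred = cf.predict_rates(fit, expo, scenario_pair, births)
        lo, hi = pred.ci["difference"][0.95]
        assert lo <= true_diff <= hi
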