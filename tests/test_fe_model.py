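"""Within transformation, OLS, cluster-robust covariance and fit statistics,
checked against explicit dummy-variable regression and hand computation."""

import numpy as np
import pandas as pd
import pytest

from heatbands import fe_model
from heatbands.fe_model import (
    FEFit,
    ModelSpec,
    absorb_fixed_effects,
    build_design,
    cluster_robust_vcov,
    fit_statistics,
    fit_within_ols,
    joint_wald_F,
)


def small_instance(seed=5, n=400, k=4):
    """A two-way FE instance small enough for the dummy-variable oracle."""
    rng = np.random.default_rng(seed)
    loc = rng.integers(0, 12, n)
    month = rng.integers(1, 13, n)
    sex = rng.integers(0, 2, n)
    ym = rng.integers(0, 18, n)
    cl = loc % 7
    fe1 = pd.factorize(pd.Series(loc * 100 + month * 2 + sex))[0]
    fe2 = pd.factorize(pd.Series(ym))[0]
    X = rng.standard_normal((n, k))
    beta = np.array([0.5, -0.2, 0.0, 0.1])[:k]
    # cluster-correlated errors
    u = rng.standard_normal(cl.max() + 1)[cl] * 0.5 + rng.standard_normal(n)
    y = X @ beta + u + 0.3 * rng.standard_normal(fe1.max() + 1)[fe1]
    return y, X, fe1, fe2, cl


def dummy_path(y, X, fe1, fe2, cl):
    """Oracle: explicit dummy OLS with a hand-computed cluster sandwich."""
    n, k = X.shape
    L1, L2 = fe1.max() + 1, fe2.max() + 1
    D1 = np.zeros((n, L1))
    D1[np.arange(n), fe1] = 1
    D2 = np.zeros((n, L2))
    D2[np.arange(n), fe2] = 1
    W = np.column_stack([X, D1, D2[:, 1:]])
    bfull, *_ = np.linalg.lstsq(W, y, rcond=None)
    resid = y - W @ bfull
    XtXi = np.linalg.pinv(W.T @ W)
    G = cl.max() + 1
    meat = np.zeros((W.shape[1], W.shape[1]))
    for g in range(G):
        sg = (W[cl == g] * resid[cl == g, None]).sum(axis=0)
        meat += np.outer(sg, sg)
    K = W.shape[1]
    V = (G / (G - 1)) * ((n - 1) / (n - K)) * XtXi @ meat @ XtXi
    D = np.column_stack([D1, D2[:, 1:]])
    my = y - D @ np.linalg.lstsq(D, y, rcond=None)[0]
    r2w = 1 - resid @ resid / (my @ my)
    return bfull[:k], V[:k, :k], resid, r2w


class TestAbsorption:
    def test_single_group_one_pass_exact(self):
        rng = np.random.default_rng(1)
        codes = rng.integers(0, 5, 100)
        y = rng.standard_normal(100)
        X = rng.standard_normal((100, 2))
        yd, Xd, sweeps = absorb_fixed_effects(y, X, [codes])
        assert sweeps == 1
        for g in range(5):
            assert yd[codes == g].sum() == pytest.approx(0.0, abs=1e-12)
            assert Xd[codes == g].sum(axis=0) == pytest.approx(0.0, abs=1e-12)

    def test_residuals_orthogonal_to_fe_indicators(self):
        y, X, fe1, fe2, cl = small_instance()
        yd, Xd, _ = absorb_fixed_effects(y, X, [fe1, fe2])
        for codes in (fe1, fe2):
            for g in range(codes.max() + 1):
                assert abs(yd[codes == g].sum()) < 1e-8
                assert np.abs(Xd[codes == g].sum(axis=0)).max() < 1e-8

    def test_constant_column_demeaned_to_zero(self):
        y, X, fe1, fe2, cl = small_instance()
        Xc = np.column_stack([X, np.ones(len(y))])
        _, Xd, _ = absorb_fixed_effects(y, Xc, [fe1, fe2])
        assert np.abs(Xd[:, -1]).max() < 1e-8

    def test_requires_a_group(self):
        with pytest.raises(ValueError):
            absorb_fixed_effects(np.ones(3), np.ones((3, 1)), [])


class TestDummyVariableOracle:
    def test_two_way_fe_matches_explicit_dummies(self):
        y, X, fe1, fe2, cl = small_instance()
        yd, Xd, _ = absorb_fixed_effects(y, X, [fe1, fe2])
        beta, resid, keep, dropped = fit_within_ols(yd, Xd, [f"x{i}" for i in range(4)])
        assert dropped == []
        b_oracle, V_oracle, resid_oracle, r2w_oracle = dummy_path(y, X, fe1, fe2, cl)
        np.testing.assert_allclose(beta, b_oracle, rtol=1e-8)
        np.testing.assert_allclose(resid, resid_oracle, rtol=0, atol=1e-8)
        df_abs = (fe1.max() + 1) + (fe2.max() + 1) - 1
        V = cluster_robust_vcov(Xd[:, keep], resid, cl, k_total=4 + df_abs)
        np.testing.assert_allclose(V, V_oracle, rtol=1e-6)
        r2w = 1 - resid @ resid / (yd @ yd)
        assert r2w == pytest.approx(r2w_oracle, rel=1e-8)

    def test_statsmodels_cross_check(self):
        sm = pytest.importorskip("statsmodels.api")
        y, X, fe1, fe2, cl = small_instance(seed=6)
        n, k = X.shape
        L1, L2 = fe1.max() + 1, fe2.max() + 1
        D1 = np.zeros((n, L1))
        D1[np.arange(n), fe1] = 1
        D2 = np.zeros((n, L2))
        D2[np.arange(n), fe2] = 1
        W = np.column_stack([X, D1, D2[:, 1:]])
        res = sm.OLS(y, W).fit(cov_type="cluster", cov_kwds={"groups": cl})
        yd, Xd, _ = absorb_fixed_effects(y, X, [fe1, fe2])
        beta, resid, keep, _ = fit_within_ols(yd, Xd, [f"x{i}" for i in range(k)])
        np.testing.assert_allclose(beta, res.params[:k], rtol=1e-7)
        df_abs = L1 + L2 - 1
        V = cluster_robust_vcov(Xd[:, keep], resid, cl, k_total=k + df_abs)
        np.testing.assert_allclose(
            np.sqrt(np.diag(V)), res.bse[:k], rtol=1e-6
        )


class TestWithinOLS:
    def test_exact_linear_outcome_recovered(self):
        rng = np.random.default_rng(2)
        codes = rng.integers(0, 8, 200)
        X = rng.standard_normal((200, 1))
        y = 2.5 * X[:, 0] + rng.standard_normal(8)[codes]
        yd, Xd, _ = absorb_fixed_effects(y, X, [codes])
        beta, resid, _, _ = fit_within_ols(yd, Xd, ["x"])
        assert beta[0] == pytest.approx(2.5, abs=1e-10)

    def test_duplicate_column_dropped_estimates_unchanged(self):
        y, X, fe1, fe2, cl = small_instance()
        yd, Xd, _ = absorb_fixed_effects(y, X, [fe1, fe2])
        b1, *_ = fit_within_ols(yd, Xd, [f"x{i}" for i in range(4)])
        Xdup = np.column_stack([Xd, Xd[:, 0]])
        b2, _, keep, dropped = fit_within_ols(yd, Xdup, ["x0", "x1", "x2", "x3", "x0_copy"])
        assert len(dropped) == 1
        fitted1 = Xd @ b1
        fitted2 = Xdup[:, keep] @ b2
        np.testing.assert_allclose(fitted1, fitted2, atol=1e-8)


class TestClusterVcov:
    def test_hand_computed_two_cluster_meat(self):
        X = np.array([[1.0], [2.0], [-1.0], [0.5], [1.5], [-2.0]])
        e = np.array([0.1, -0.2, 0.3, -0.1, 0.2, 0.05])
        cl = np.array([0, 0, 0, 1, 1, 1])
        s0 = (X[:3, 0] * e[:3]).sum()
        s1 = (X[3:, 0] * e[3:]).sum()
        bread = 1.0 / (X[:, 0] @ X[:, 0])
        k_total = 1
        factor = (2 / 1) * (5 / (6 - k_total))
        expected = factor * bread * (s0**2 + s1**2) * bread
        V = cluster_robust_vcov(X, e, cl, k_total=k_total)
        assert V[0, 0] == pytest.approx(expected)

    def test_singleton_clusters_equal_hc_sandwich(self):
        rng = np.random.default_rng(3)
        X = rng.standard_normal((50, 2))
        e = rng.standard_normal(50)
        cl = np.arange(50)
        V = cluster_robust_vcov(X, e, cl, k_total=2)
        bread = np.linalg.inv(X.T @ X)
        hc = (50 / 49) * (49 / 48) * bread @ ((X * (e**2)[:, None]).T @ X) @ bread
        np.testing.assert_allclose(V, hc, rtol=1e-10)

    def test_single_cluster_refused(self):
        with pytest.raises(ValueError):
            cluster_robust_vcov(np.ones((4, 1)), np.ones(4), np.zeros(4, dtype=int), 1)

    def test_homoskedastic_large_g_agrees_with_classical(self):
        rng = np.random.default_rng(7)
        n = 4000
        X = rng.standard_normal((n, 2))
        e = rng.standard_normal(n)
        cl = rng.integers(0, 200, n)
        V = cluster_robust_vcov(X, e, cl, k_total=2)
        s2 = e @ e / (n - 2)
        Vc = s2 * np.linalg.inv(X.T @ X)
        np.testing.assert_allclose(np.diag(V), np.diag(Vc), rtol=0.25)


def _toy_fit(params, vcov, heat_cols, g=30, n=1000, rss=90.0, tss=100.0, k=None, df_abs=100):
    k = k if k is not None else len(params)
    idx = list(params.keys())
    return FEFit(
        params=pd.Series(params),
        vcov=pd.DataFrame(vcov, index=idx, columns=idx),
        resid=np.zeros(n),
        n_obs=n,
        n_clusters=g,
        rss=rss,
        tss_within=tss,
        k=k,
        df_absorbed=df_abs,
        dropped=[],
        heat_terms={"m": heat_cols},
        y_mean=0.1,
    )


class TestWaldF:
    def test_zero_coefficients_give_zero_F(self):
        fit = _toy_fit({"a": 0.0, "b": 0.0}, np.eye(2) * 0.01, ["a", "b"])
        f, df1, df2, p = joint_wald_F(fit, "m")
        assert f == 0.0 and p == pytest.approx(1.0)
        assert (df1, df2) == (2, 29)

    def test_single_term_equals_squared_t(self):
        fit = _toy_fit({"a": 0.03}, np.array([[0.0001]]), ["a"])
        f, df1, _, _ = joint_wald_F(fit, "m")
        t = 0.03 / 0.01
        assert df1 == 1
        assert f == pytest.approx(t**2)

    def test_matches_dummy_path_wald(self):
        y, X, fe1, fe2, cl = small_instance(seed=8)
        yd, Xd, _ = absorb_fixed_effects(y, X, [fe1, fe2])
        beta, resid, keep, _ = fit_within_ols(yd, Xd, ["x0", "x1", "x2", "x3"])
        df_abs = (fe1.max() + 1) + (fe2.max() + 1) - 1
        V = cluster_robust_vcov(Xd[:, keep], resid, cl, k_total=4 + df_abs)
        b_o, V_o, *_ = dummy_path(y, X, fe1, fe2, cl)
        w = beta[:2] @ np.linalg.solve(V[:2, :2], beta[:2]) / 2
        w_o = b_o[:2] @ np.linalg.solve(V_o[:2, :2], b_o[:2]) / 2
        assert w == pytest.approx(w_o, rel=1e-6)


class TestFitStatistics:
    def test_pure_noise_adjusted_r2_near_zero(self):
        rng = np.random.default_rng(10)
        n = 5000
        codes = rng.integers(0, 50, n)
        y = rng.standard_normal(n)
        X = rng.standard_normal((n, 3))
        yd, Xd, _ = absorb_fixed_effects(y, X, [codes])
        beta, resid, keep, _ = fit_within_ols(yd, Xd, ["a", "b", "c"])
        fit = _toy_fit(
            dict(zip("abc", beta)), np.eye(3), ["a", "b", "c"],
            n=n, rss=float(resid @ resid), tss=float(yd @ yd), df_abs=50,
        )
        adj, _ = fit_statistics(fit)
        assert abs(adj) < 0.01

    def test_aic_ranking_matches_rss_for_equal_k(self):
        f1 = _toy_fit({"a": 0.1}, np.eye(1), ["a"], rss=80.0)
        f2 = _toy_fit({"a": 0.1}, np.eye(1), ["a"], rss=90.0)
        _, aic1 = fit_statistics(f1)
        _, aic2 = fit_statistics(f2)
        assert aic1 < aic2

    def test_useless_regressor_raises_aic(self):
        # identical fit with one extra parameter and unchanged RSS
        f1 = _toy_fit({"a": 0.1}, np.eye(1), ["a"], rss=80.0, k=1)
        f2 = _toy_fit({"a": 0.1}, np.eye(1), ["a"], rss=80.0, k=2)
        _, aic1 = fit_statistics(f1)
        _, aic2 = fit_statistics(f2)
        assert aic2 == pytest.approx(aic1 + 2.0)

    def test_zero_rss_rejected(self):
        f = _toy_fit({"a": 0.1}, np.eye(1), ["a"], rss=0.0)
        with pytest.raises(ValueError):
            fit_statistics(f)


class TestBuildDesign:
    def test_heat_column_counts(self, null_cohort):
        for m, expect in (("benchmark", 15), ("max_and_min", 30)):
            expo = null_cohort["exposures"][m]
            cols = [c for c in expo.columns if c not in expo.attrs["omitted"]]
            assert len(cols) == expect

    def test_omitted_band_refused(self, null_cohort, study):
        expo = null_cohort["exposures"]["benchmark"]
        bad = expo.attrs["omitted"][0]
        with pytest.raises(ValueError, match="omitted"):
            build_design(
                null_cohort["births"],
                expo,
                ModelSpec(heat_terms={"benchmark": [bad]}),
                cluster_map=study["assignment"].assignment,
            )

    def test_covariates_only_model_fits(self, null_cohort, study):
        design = build_design(
            null_cohort["births"], None, ModelSpec(heat_terms={}),
            cluster_map=study["assignment"].assignment,
        )
        fit = fe_model.fit_fe_model(design)
        assert fit.k >= 6  # first_pregnancy, aboriginal, age one-hots

    def test_parameter_recovery_point_estimates(self, planted_cohort):
        # one realised cohort: all planted coefficients within 3 SEs
        from heatbands import synthetic_data as sd

        fit = planted_cohort["solvers"]["max_and_min"].fit()
        for name, truth in sd.MODERATE_BAND_EFFECTS.items():
            est = fit.params[name]
            se = fit.bse[name]
            assert abs(est - truth) < 3 * se, name
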