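"""Design construction and the mixed logistic likelihood machinery."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy.special import expit

from grazerange.design import INTERCEPT, ModelSpec, build_design
from grazerange.glmm import (MixedLogit, aic_select, check_collinearity,
                             nakagawa_r2_from_variances, r2_nakagawa)


def _labelled_frame(n=60, seed=0):
    rng = np.random.default_rng(seed)
    return pd.DataFrame({
        "response": rng.integers(0, 2, n),
        "animal_id": rng.choice(["a", "b", "c"], n),
        "treatment": rng.choice(["before", "early", "ongoing", "after"], n),
        "tod": rng.choice(["day", "night", "twilight"], n),
        "calving": rng.integers(0, 2, n).astype(float),
        "rut": rng.integers(0, 2, n).astype(float),
        "cover_s": rng.standard_normal(n),
        "ndvi_s": rng.standard_normal(n),
        "dist_site_s": rng.standard_normal(n),
    })


class TestBuildDesign:
    def test_factor_dummy_counts(self):
        df = _labelled_frame()
        X, y, g = build_design(df, ModelSpec(["tod"]))
        assert list(X.columns) == [INTERCEPT, "tod[night]", "tod[twilight]"]

    def test_full_interaction_column_count(self):
        df = _labelled_frame()
        X, _, _ = build_design(df, ModelSpec(["treatment:tod"]))
        # (4-1) x (3-1) product columns plus intercept
        assert X.shape[1] == 1 + 6

    def test_interaction_is_elementwise_product(self):
        df = _labelled_frame()
        X, _, _ = build_design(df, ModelSpec(["dist", "treatment",
                                              "dist:treatment"]))
        manual = (df["dist_site_s"].to_numpy()
                  * (df["treatment"] == "early").to_numpy())
        np.testing.assert_allclose(X["dist:treatment[early]"], manual)

    def test_quadratic_of_scaled(self):
        df = _labelled_frame()
        X, _, _ = build_design(df, ModelSpec(["cover", "cover2"]))
        np.testing.assert_allclose(X["cover2"], df["cover_s"] ** 2)

    def test_deterministic_column_order(self):
        df = _labelled_frame()
        spec = ModelSpec(["cover", "treatment", "tod", "dist:treatment:tod"])
        cols1 = list(build_design(df, spec)[0].columns)
        cols2 = list(build_design(df.copy(), spec)[0].columns)
        assert cols1 == cols2

    def test_unknown_term_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            ModelSpec(["elevation"])

    def test_scenario_reindex_fills_absent_levels(self):
        df = _labelled_frame().assign(treatment="before")
        X, _, _ = build_design(df, ModelSpec(["treatment"]),
                               columns=[INTERCEPT, "treatment[early]"])
        assert (X["treatment[early]"] == 0).all()


@pytest.fixture(scope="module")
def tiny_fixture():
    """20 observations in 2 groups with a known design."""
    rng = np.random.default_rng(3)
    X = np.column_stack([np.ones(20), rng.standard_normal(20)])
    g = np.repeat([0, 1], 10)
    u = np.array([0.7, -0.5])
    y = (rng.random(20) < expit(X @ np.array([0.2, 0.8]) + u[g])).astype(float)
    return pd.DataFrame(X, columns=[INTERCEPT, "x"]), y, g


def brute_force_loglik(X, y, g, beta, sigma, ngrid=4001, span=8.0):
    """Fine fixed-grid quadrature over the random effect (oracle)."""
    eta = X @ np.asarray(beta)
    us = np.linspace(-span * sigma, span * sigma, ngrid)
    prior = np.exp(-0.5 * (us / sigma) ** 2) / (sigma * np.sqrt(2 * np.pi))
    ll = 0.0
    for gi in np.unique(g):
        idx = g == gi
        e = eta[idx][:, None] + us[None, :]
        p = expit(e)
        lik = np.prod(np.where(y[idx][:, None] == 1, p, 1 - p), axis=0)
        ll += np.log(np.trapezoid(lik * prior, us))
    return ll


class TestMixedLogit:
    def test_loglik_matches_bruteforce_quadrature(self, tiny_fixture):
        Xdf, y, g = tiny_fixture
        m = MixedLogit(y, Xdf, g)
        X = Xdf.to_numpy()
        for beta, sigma in [([0.2, 0.8], 0.7), ([0.0, 0.0], 0.3),
                            ([1.0, -1.0], 1.5), ([-0.5, 0.4], 0.05)]:
            ours = m.loglike(np.array(list(beta) + [sigma]))
            oracle = brute_force_loglik(X, y, g, beta, sigma)
            assert ours == pytest.approx(oracle, abs=1e-4)

    def test_mle_beats_parameter_grid_search(self, tiny_fixture):
        Xdf, y, g = tiny_fixture
        m = MixedLogit(y, Xdf, g)
        fit = m.fit(quad_points=15)
        X = Xdf.to_numpy()
        best = -np.inf
        for b0 in np.linspace(-2, 2, 9):
            for b1 in np.linspace(-2, 2, 9):
                for s in (0.1, 0.3, 0.7, 1.2, 2.0):
                    best = max(best,
                               brute_force_loglik(X, y, g, [b0, b1], s))
        assert fit.llf >= best - 1e-6

    def test_sigma_zero_matches_irls_oracle(self, clustered_logit_data):
        d = clustered_logit_data
        fit = MixedLogit(d["y"], d["X"], d["groups"]).fit(re_sd=0.0)
        oracle = sm.Logit(d["y"], d["X"].to_numpy()).fit(disp=0)
        np.testing.assert_allclose(fit.params.to_numpy(), oracle.params,
                                   atol=1e-4)
        assert fit.llf == pytest.approx(oracle.llf, abs=1e-6)

    def test_null_variance_recovered(self):
        # p = 0.25 everywhere, no clustering: intercept = logit(0.25)
        rng = np.random.default_rng(11)
        n = 10_000
        y = (rng.random(n) < 0.25).astype(float)
        X = pd.DataFrame({INTERCEPT: np.ones(n)})
        g = np.arange(n) % 20
        fit = MixedLogit(y, X, g).fit()
        assert fit.params[INTERCEPT] == pytest.approx(np.log(1 / 3), abs=0.1)
        assert fit.re_var < 0.01

    def test_random_intercept_sd_recovery(self, clustered_logit_data):
        d = clustered_logit_data
        fit = MixedLogit(d["y"], d["X"], d["groups"]).fit()
        assert 0.7 <= fit.re_sd <= 1.3
        np.testing.assert_allclose(fit.params.to_numpy(), d["beta"], atol=0.15)

    def test_quadrature_node_stability(self, tiny_fixture):
        Xdf, y, g = tiny_fixture
        m = MixedLogit(y, Xdf, g)
        p = np.array([0.2, 0.8, 0.7])
        assert abs(m.loglike(p, 9) - m.loglike(p, 25)) < 1e-3

    def test_aic_identity(self, tiny_fixture):
        Xdf, y, g = tiny_fixture
        fit = MixedLogit(y, Xdf, g).fit()
        k = len(fit.params)
        assert fit.aic == pytest.approx(-2 * fit.llf + 2 * (k + 1))

    def test_constant_response_rejected(self, tiny_fixture):
        Xdf, _, g = tiny_fixture
        with pytest.raises(ValueError):
            MixedLogit(np.ones(20), Xdf, g)

    def test_separation_flagged_not_fatal(self):
        rng = np.random.default_rng(1)
        n = 200
        x = rng.standard_normal(n)
        y = (x > 0).astype(float)  # perfectly separated
        X = pd.DataFrame({INTERCEPT: np.ones(n), "x": x})
        g = np.arange(n) % 4
        fit = MixedLogit(y, X, g).fit(re_sd=0.0)
        assert any("separation" in w for w in fit.warnings)

    def test_summary_mentions_key_quantities(self, tiny_fixture):
        Xdf, y, g = tiny_fixture
        s = MixedLogit(y, Xdf, g).fit().summary()
        for token in ("logLik", "AIC", "random-intercept SD", "x"):
            assert token in s


class TestCollinearity:
    def test_orthogonal_columns_gvif_one(self):
        rng = np.random.default_rng(0)
        q, _ = np.linalg.qr(rng.standard_normal((200, 3)))
        q -= q.mean(axis=0)  # orthogonalise the centred columns
        q, _ = np.linalg.qr(q)
        X = pd.DataFrame(q, columns=["a", "b", "c"])
        X.insert(0, INTERCEPT, 1.0)
        _, gvif = check_collinearity(X)
        np.testing.assert_allclose(gvif["GVIF"], 1.0, atol=1e-8)

    def test_pairwise_r09_gives_vif_5p26(self):
        rng = np.random.default_rng(1)
        n = 100_000
        a = rng.standard_normal(n)
        b = 0.9 * a + np.sqrt(1 - 0.81) * rng.standard_normal(n)
        X = pd.DataFrame({INTERCEPT: np.ones(n), "a": a, "b": b})
        corr, gvif = check_collinearity(X)
        assert corr.loc["a", "b"] == pytest.approx(0.9, abs=0.01)
        assert gvif.loc["a", "GVIF"] == pytest.approx(1 / (1 - 0.81),
                                                      rel=0.05)

    def test_duplicated_column_rejected(self):
        a = np.arange(10.0)
        X = pd.DataFrame({INTERCEPT: 1.0, "a": a, "b": a})
        with pytest.raises(ValueError):
            check_collinearity(X)


class TestSelectionAndR2:
    class _Fake:
        def __init__(self, aic, nobs=100):
            self.aic = aic
            self.nobs = nobs

    def test_delta_aic_10_is_decisive(self):
        w, table, decisive = aic_select([self._Fake(100), self._Fake(112)],
                                        ["m0", "m1"])
        assert w.aic == 100 and decisive
        assert table["dAIC"].tolist() == [0.0, 12.0]

    def test_small_gap_not_decisive(self):
        w, _, decisive = aic_select([self._Fake(100), self._Fake(104)])
        assert w.aic == 100 and not decisive

    def test_tie_not_decisive(self):
        _, _, decisive = aic_select([self._Fake(100), self._Fake(100)])
        assert not decisive

    def test_mismatched_nobs_rejected(self):
        with pytest.raises(ValueError):
            aic_select([self._Fake(1, 50), self._Fake(2, 60)])

    def test_nakagawa_closed_form(self):
        marg, cond = nakagawa_r2_from_variances(1.0, 1.0)
        assert marg == pytest.approx(0.1890, abs=5e-4)
        assert cond == pytest.approx(0.3779, abs=5e-4)

    def test_zero_re_variance_marginal_equals_conditional(self):
        marg, cond = nakagawa_r2_from_variances(2.0, 0.0)
        assert marg == cond

    def test_r2_from_fit_in_unit_interval(self, clustered_logit_data):
        d = clustered_logit_data
        fit = MixedLogit(d["y"], d["X"], d["groups"]).fit()
        marg, cond = r2_nakagawa(fit)
        assert 0 < marg <= cond < 1


class TestPredictResponse:
    def test_reference_scenario_inverse_logit_of_intercept(self, tiny_fixture):
        # intercept-only model: population prediction = expit(intercept)
        rng = np.random.default_rng(2)
        n = 500
        y = (rng.random(n) < 0.009).astype(float)
        df = pd.DataFrame({
            "use": y, "animal_id": np.arange(n) % 5,
            "treatment": "before", "tod": "day",
            "calving": 0.0, "rut": 0.0,
        })
        spec = ModelSpec(["tod"], response="use", group="animal_id")
        X, yy, g = build_design(df, spec)
        X = X[[INTERCEPT]]  # tod columns are void here anyway
        fit = MixedLogit(yy, X, g).fit(re_sd=0.0)
        pred = fit.predict_response({}, ModelSpec([]))
        assert pred == pytest.approx(expit(fit.params[INTERCEPT]), abs=1e-12)

    def test_table_intercept_value(self):
        # a use-model intercept of -4.6966 corresponds to p ~ 0.009
        assert expit(-4.6966) == pytest.approx(0.0090, abs=2e-4)

    def test_monotone_in_covariate(self):
        rng = np.random.default_rng(6)
        df = _labelled_frame(2000, seed=6)
        df["response"] = (rng.random(2000)
                          < expit(1.0 * df["cover_s"])).astype(float)
        spec = ModelSpec(["cover"])
        X, y, g = build_design(df, spec)
        fit = MixedLogit(y, X, g).fit(re_sd=0.0)
        preds = [fit.predict_response({"cover_s": v}, spec)
                 for v in (-1.0, 0.0, 1.0)]
        assert preds[0] < preds[1] < preds[2]
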