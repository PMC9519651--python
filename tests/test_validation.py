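"""Binned rank-correlation validation and ground-truth recovery tools."""

import numpy as np
import pandas as pd
import pytest

from grazerange.covariates import Scaler
from grazerange.design import INTERCEPT, ModelSpec
from grazerange.validation import (boyce_spearman, kfold_cv,
                                   rescale_coefficients)


class TestBoyceSpearman:
    def test_perfect_ranking_rho_one(self):
        rng = np.random.default_rng(0)
        avail = rng.uniform(0, 1, 5000)
        # used drawn proportional to score -> adjusted frequency increasing
        used = rng.choice(avail, size=2000, p=avail / avail.sum())
        rho, table = boyce_spearman(used, avail, n_bins=10)
        assert rho == pytest.approx(1.0)
        assert np.all(np.diff(table["adjusted_freq"]) > 0)

    def test_inverted_ranking_rho_minus_one(self):
        # deterministic construction: used counts strictly decreasing over
        # the ten availability deciles
        avail = np.linspace(0.0, 1.0, 5000)
        centers = np.linspace(0.05, 0.95, 10)
        used = np.repeat(centers, np.arange(100, 0, -10))
        rho, _ = boyce_spearman(used, avail, n_bins=10)
        assert rho == pytest.approx(-1.0)

    def test_random_scores_near_zero_over_seeds(self):
        rhos = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            rhos.append(boyce_spearman(rng.uniform(0, 1, 600),
                                       rng.uniform(0, 1, 9600))[0])
        assert abs(np.mean(rhos)) < 0.5

    def test_tied_scores_merge_bins(self):
        avail = np.concatenate([np.zeros(500), np.linspace(0, 1, 500)])
        used = np.linspace(0, 1, 100)
        rho, table = boyce_spearman(used, avail, n_bins=10)
        assert len(table) < 10
        assert np.isfinite(rho)

    def test_empty_inputs_rejected(self):
        with pytest.raises(ValueError):
            boyce_spearman([], [1.0, 2.0])


def _synthetic_rsf_data(seed, n_animals=6, n_used=300, ratio=8,
                        hetero=0.0):
    """LabelledPoint-style frame from a known one-covariate RSF.

    Each animal has its own covariate availability (mean shifted by
    ``hetero`` x animal effect), used points drawn with weight exp(beta*x).
    """
    rng = np.random.default_rng(seed)
    beta = 1.2
    frames = []
    for a in range(n_animals):
        shift = hetero * rng.standard_normal()
        avail_x = rng.standard_normal(n_used * ratio) + shift
        used_pool = rng.standard_normal(4000) + shift
        w = np.exp(beta * used_pool)
        used_x = rng.choice(used_pool, size=n_used, p=w / w.sum())
        frames.append(pd.DataFrame({
            "animal_id": f"a{a}",
            "response": np.r_[np.ones(n_used), np.zeros(n_used * ratio)],
            "pair_id": np.r_[np.arange(n_used),
                             np.repeat(np.arange(n_used), ratio)],
            "cover_s": np.r_[used_x, avail_x],
        }))
    df = pd.concat(frames, ignore_index=True)
    df["treatment"] = "before"
    df["tod"] = "day"
    df["calving"] = 0.0
    df["rut"] = 0.0
    df["ndvi_s"] = 0.0
    df["dist_site_s"] = 0.0
    return df, beta


class TestKfoldCv:
    def test_true_model_scores_rank_well(self):
        df, beta = _synthetic_rsf_data(0, n_used=400)
        out = kfold_cv(df, ModelSpec(["cover"]), k=5, blocking="random",
                       seed=0, score_fn=lambda d: beta * d["cover_s"])
        assert out.attrs["mean_rho"] >= 0.9

    def test_refit_recovers_ranking(self):
        df, _ = _synthetic_rsf_data(1)
        out = kfold_cv(df, ModelSpec(["cover"]), k=3, blocking="random",
                       seed=1, quad_points=9)
        assert out.attrs["mean_rho"] >= 0.8
        assert len(out) == 3

    def test_blocked_folds_keep_animals_whole(self):
        df, _ = _synthetic_rsf_data(2)
        from grazerange.validation import _assign_folds

        folds = _assign_folds(df, 3, "by_animal", seed=0)
        per_animal = pd.DataFrame({"a": df["animal_id"], "f": folds}).groupby(
            "a")["f"].nunique()
        assert (per_animal == 1).all()

    def test_blocked_not_better_than_random_under_heterogeneity(self):
        # directional property: with animal-level covariate shifts, scoring
        # transfers worse across animals than within them (on average)
        diffs = []
        for seed in range(20):
            df, beta = _synthetic_rsf_data(seed, n_animals=6, n_used=150,
                                           ratio=6, hetero=1.5)
            fn = lambda d: beta * d["cover_s"]
            r_rand = kfold_cv(df, ModelSpec(["cover"]), k=3,
                              blocking="random", seed=seed,
                              score_fn=fn).attrs["mean_rho"]
            r_block = kfold_cv(df, ModelSpec(["cover"]), k=3,
                               blocking="by_animal", seed=seed,
                               score_fn=fn).attrs["mean_rho"]
            diffs.append(r_block - r_rand)
        assert np.mean(diffs) <= 0.05

    def test_too_few_animals_for_blocking(self):
        df, _ = _synthetic_rsf_data(3, n_animals=3)
        with pytest.raises(ValueError):
            kfold_cv(df, ModelSpec(["cover"]), k=5, blocking="by_animal")


class TestRescaleCoefficients:
    def test_exact_roundtrip_on_constructed_quadratic(self):
        # beta under one scaling, re-expressed under another, is an exact
        # linear map: verify against direct algebra on eta
        fit_sc = Scaler(means={"dist_site": 500.0}, sds={"dist_site": 300.0})
        ref_sc = Scaler(means={"dist_site": 900.0}, sds={"dist_site": 600.0})
        params = pd.Series({INTERCEPT: -1.0, "dist": -0.7, "dist2": -0.3,
                            "treatment[early]": 0.4,
                            "dist:treatment[early]": 0.25})
        cov = np.eye(len(params)) * 0.01
        beta_r, _ = rescale_coefficients(params, cov, fit_sc, ref_sc)

        rng = np.random.default_rng(0)
        d = rng.uniform(0, 2000, 50)
        for early in (0.0, 1.0):
            zf = (d - 500.0) / 300.0
            zr = (d - 900.0) / 600.0
            eta_f = (params[INTERCEPT] + params["dist"] * zf
                     + params["dist2"] * zf ** 2
                     + params["treatment[early]"] * early
                     + params["dist:treatment[early]"] * zf * early)
            eta_r = (beta_r.get(INTERCEPT, 0) + beta_r["dist"] * zr
                     + beta_r["dist2"] * zr ** 2
                     + beta_r.get("treatment[early]", 0) * early
                     + beta_r["dist:treatment[early]"] * zr * early)
            np.testing.assert_allclose(eta_r, eta_f, rtol=1e-10)

    def test_identity_scaling_is_noop(self):
        sc = Scaler(means={"dist_site": 100.0}, sds={"dist_site": 50.0})
        params = pd.Series({"dist": -0.7, "dist2": -0.3})
        beta_r, cov_r = rescale_coefficients(params, np.eye(2), sc, sc)
        assert beta_r["dist"] == pytest.approx(-0.7)
        assert beta_r["dist2"] == pytest.approx(-0.3)
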