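"""Predictive validation and ground-truth recovery checks.

Cross-validation follows the binned, area-adjusted frequency approach used
for habitat-suitability models: held-out RSF scores are binned into
quantile bins of the held-out *available* score distribution, the
area-adjusted use frequency per bin is (share of used points in the bin) /
(share of available points in the bin), and the Spearman rank correlation
between bin rank and adjusted frequency measures how monotonically the
model orders habitat.  Folds are either random (stratified within animal,
paired availability points travel with their used fix) or blocked by whole
animals to probe transferability across individuals.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import comb

from .design import CONT_BASIS, INTERCEPT, ModelSpec
from .glmm import MixedLogit, MixedLogitResults
from .synthetic import TrueModel

logger = logging.getLogger(__name__)


def boyce_spearman(used_scores, avail_scores, n_bins: int = 10):
    """Spearman rho between score-bin rank and area-adjusted use frequency.

    Bins are quantile bins of the available-score distribution (equal
    availability mass); duplicate quantile edges (score ties) merge bins,
    with a log note.  Returns (rho, per-bin table).
    """
    used = np.asarray(used_scores, dtype=float)
    avail = np.asarray(avail_scores, dtype=float)
    used = used[np.isfinite(used)]
    avail = avail[np.isfinite(avail)]
    if used.size == 0 or avail.size == 0:
        raise ValueError("need used and available scores")
    edges = np.quantile(avail, np.linspace(0.0, 1.0, n_bins + 1))
    edges = np.unique(edges)
    if len(edges) - 1 < n_bins:
        logger.info("tied score quantiles: %d bins merged to %d",
                    n_bins, len(edges) - 1)
    if len(edges) < 3:
        raise ValueError("scores too degenerate to bin")
    inner = edges[1:-1]
    u_bin = np.searchsorted(inner, used, side="right")
    a_bin = np.searchsorted(inner, avail, side="right")
    nb = len(edges) - 1
    u_cnt = np.bincount(u_bin, minlength=nb).astype(float)
    a_cnt = np.bincount(a_bin, minlength=nb).astype(float)
    keep = a_cnt > 0
    u_share = u_cnt[keep] / used.size
    a_share = a_cnt[keep] / avail.size
    adjusted = u_share / a_share
    ranks = np.arange(nb)[keep]
    rho = stats.spearmanr(ranks, adjusted).statistic
    table = pd.DataFrame({"bin": ranks, "used_share": u_share,
                          "avail_share": a_share, "adjusted_freq": adjusted})
    return float(rho), table


def _assign_folds(data: pd.DataFrame, k: int, blocking: str, seed: int
                  ) -> np.ndarray:
    rng = np.random.default_rng(seed)
    animals = sorted(data["animal_id"].unique())
    fold = np.full(len(data), -1, dtype=int)
    if blocking == "by_animal":
        if len(animals) < k:
            raise ValueError("blocked CV needs at least k animals")
        sizes = data.groupby("animal_id").size().loc[animals]
        load = np.zeros(k)
        for animal in sizes.sort_values(ascending=False).index:
            f = int(np.argmin(load))
            fold[(data["animal_id"] == animal).to_numpy()] = f
            load[f] += sizes[animal]
    elif blocking == "random":
        # stratified: each animal's used/available pairs spread over folds
        for animal in animals:
            mask = (data["animal_id"] == animal).to_numpy()
            pairs = data.loc[mask, "pair_id"].to_numpy()
            uniq = np.unique(pairs)
            perm = rng.permutation(len(uniq))
            pair_fold = dict(zip(uniq[perm], np.arange(len(uniq)) % k))
            fold[mask] = [pair_fold[p] for p in pairs]
    else:
        raise ValueError(f"unknown blocking {blocking!r}")
    return fold


def kfold_cv(data: pd.DataFrame, spec: ModelSpec, k: int = 5,
             blocking: str = "random", n_bins: int = 10, seed: int = 0,
             score_fn=None, quad_points: int = 15) -> pd.DataFrame:
    """Fold-wise Boyce-style validation of an RSF specification.

    For each fold the model is refitted on the training data (same term
    list, no per-fold reselection) and the held-out used and available
    points are scored by the fixed-effect linear predictor (the RSF score,
    up to the irrelevant intercept).  ``score_fn(test_df) -> scores``
    replaces the refit, e.g. to score by a known generating model.

    Returns a table with one row per fold (fold, blocking, n_test, rho);
    the mean rho is in ``result.attrs['mean_rho']``.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    from .design import build_design  # local import to avoid cycle at module load

    fold = _assign_folds(data, k, blocking, seed)
    rows = []
    for f in range(k):
        test = data.loc[fold == f]
        train = data.loc[fold != f]
        if (test["response"] == 1).sum() == 0:
            raise ValueError(f"fold {f} has no used points")
        if score_fn is not None:
            scores = np.asarray(score_fn(test), dtype=float)
        else:
            Xtr, ytr, gtr = build_design(train, spec)
            fit = MixedLogit(ytr, Xtr, gtr).fit(quad_points=quad_points)
            Xte, _, _ = build_design(test, spec, columns=fit.params.index)
            scores = Xte.to_numpy(dtype=float) @ fit.params.to_numpy()
        used = scores[(test["response"] == 1).to_numpy()]
        avail = scores[(test["response"] == 0).to_numpy()]
        rho, _ = boyce_spearman(used, avail, n_bins=n_bins)
        rows.append({"fold": f, "blocking": blocking,
                     "n_test": len(test), "rho": rho})
    out = pd.DataFrame(rows)
    out.attrs["mean_rho"] = float(out["rho"].mean())
    return out


# ---------------------------------------------------------------------------
# parameter recovery


def _parse_column(name: str):
    """Column name -> (frozenset of dummy components, continuous var, power)."""
    if name == INTERCEPT:
        return frozenset(), None, 0
    dummies = []
    var, power = None, 0
    for comp in name.split(":"):
        if comp in CONT_BASIS:
            col, p = CONT_BASIS[comp]
            if var is not None:
                raise ValueError(f"two continuous factors in column {name!r}")
            var, power = col[:-2], p  # strip the "_s" suffix
        else:
            dummies.append(comp)
    return frozenset(dummies), var, power


def _key_label(key) -> str:
    dummies, var, power = key
    parts = []
    if var is not None:
        base = {("cover", 1): "cover", ("cover", 2): "cover2",
                ("ndvi", 1): "ndvi", ("ndvi", 2): "ndvi2",
                ("dist_site", 1): "dist", ("dist_site", 2): "dist2"}[(var, power)]
        parts.append(base)
    parts.extend(sorted(dummies))
    return ":".join(parts) if parts else INTERCEPT


def rescale_coefficients(params: pd.Series, cov: np.ndarray,
                         fit_scaling, ref_scaling):
    """Re-express fitted coefficients under a different covariate scaling.

    The fitted design used z_f = (x - m_f)/s_f; the target basis uses
    z_r = (x - m_r)/s_r, so z_f = a z_r + d with a = s_r/s_f and
    d = (m_r - m_f)/s_f.  Powers of z_f expand binomially, which makes the
    coefficient map a linear transform T; the covariance transforms as
    T' Sigma T.  Returns (Series over target keys, covariance DataFrame).
    """
    def ab(var):
        m_f = fit_scaling.means.get(var, 0.0)
        s_f = fit_scaling.sds.get(var, 1.0)
        m_r = ref_scaling.means.get(var, 0.0)
        s_r = ref_scaling.sds.get(var, 1.0)
        return s_r / s_f, (m_r - m_f) / s_f

    contributions: dict[tuple, dict[int, float]] = {}
    parsed = [_parse_column(c) for c in params.index]
    targets: list[tuple] = []
    for i, (dummies, var, power) in enumerate(parsed):
        if var is None:
            items = [((dummies, None, 0), 1.0)]
        else:
            a, d = ab(var)
            items = []
            for j in range(power + 1):
                w = comb(power, j, exact=True) * a ** j * d ** (power - j)
                tkey = (dummies, var if j > 0 else None, j)
                items.append((tkey, float(w)))
        for tkey, w in items:
            if tkey not in targets:
                targets.append(tkey)
            contributions.setdefault(tkey, {})[i] = (
                contributions.get(tkey, {}).get(i, 0.0) + w)
    T = np.zeros((len(params), len(targets)))
    for t_idx, tkey in enumerate(targets):
        for i, w in contributions[tkey].items():
            T[i, t_idx] = w
    beta_r = T.T @ params.to_numpy()
    cov_r = T.T @ np.asarray(cov) @ T
    labels = [_key_label(t) for t in targets]
    return (pd.Series(beta_r, index=labels),
            pd.DataFrame(cov_r, index=labels, columns=labels))


def recovery_report(true_model: TrueModel, fit: MixedLogitResults,
                    fit_scaling) -> pd.DataFrame:
    """Per-term comparison of a fitted model against the generating truth.

    The fitted coefficients (expressed under the data-driven scaling) are
    linearly re-expressed under the true model's reference scaling before
    comparison, so truth and estimate live in the same basis.  Only terms of
    the true model are reported: intercept and categorical main effects of
    the use-availability fit absorb within-home-range normalising constants
    and carry no spatial-selection information.
    """
    beta_r, cov_r = rescale_coefficients(
        fit.params, fit.cov_params.to_numpy(), fit_scaling, true_model.scaling)
    se_r = pd.Series(np.sqrt(np.diag(cov_r)), index=beta_r.index)
    rows = []
    for name, truth in true_model.coefficients.items():
        if name == INTERCEPT:
            continue
        key = _key_label(_parse_column(name))
        est = beta_r.get(key, np.nan)
        se = se_r.get(key, np.nan)
        rows.append({
            "term": name, "truth": truth, "estimate": est, "se": se,
            "error": est - truth,
            "abs_z": abs(est - truth) / se if se and np.isfinite(se) else np.nan,
            "sign_agree": bool(np.sign(est) == np.sign(truth))
            if np.isfinite(est) else False,
        })
    if not rows:
        raise ValueError("true model and fit share no comparable terms")
    return pd.DataFrame(rows)
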