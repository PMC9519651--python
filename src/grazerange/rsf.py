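"""Exponential resource selection functions built from fitted models.

An RSF scores habitat by ``w(x) = exp(sum_j beta_j x_j)`` over the terms of
a fitted use-availability logistic model that reached significance
(p < 0.05).  The intercept is dropped: RSF scores are relative, not
probabilities.  Scores are produced for points, for whole rasters (scenario
maps) and along distance-to-site gradients (displacement profiles).

By default individual coefficients (factor levels) are retained or dropped
on their own significance; set ``enforce_hierarchy`` to also keep parent
main effects of retained interactions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .covariates import Scaler, distance_to_sites
from .design import INTERCEPT, ModelSpec, build_design, scenario_frame
from .glmm import MixedLogitResults
from .raster import Raster
from .synthetic import _column_to_term  # shared vocabulary parser


@dataclass
class RSFModel:
    """Retained significant coefficients plus the covariate scaling."""

    coefficients: pd.Series
    scaling: Scaler
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if INTERCEPT in self.coefficients.index:
            raise ValueError("RSF coefficients must not include an intercept")

    @property
    def terms(self) -> list[str]:
        seen = []
        for name in self.coefficients.index:
            t = _column_to_term(name)
            if t not in seen:
                seen.append(t)
        return seen

    def spec(self) -> ModelSpec:
        return ModelSpec(self.terms, response="__none__", group="__none__")

    # -- scoring ---------------------------------------------------------
    def linear_predictor(self, df: pd.DataFrame) -> np.ndarray:
        X, _, _ = build_design(df, self.spec(), columns=self.coefficients.index)
        return X.to_numpy(dtype=float) @ self.coefficients.to_numpy()

    def score(self, covariates: pd.DataFrame | dict, scenario: dict | None = None
              ) -> np.ndarray:
        """RSF score w(x) for points.

        ``covariates`` supplies raw ``cover``/``ndvi``/``dist_site`` columns
        (scaled internally with the stored parameters) or ready-made ``*_s``
        columns; ``scenario`` fills/overrides the context columns
        (treatment, tod, calving, rut).
        """
        if isinstance(covariates, dict):
            covariates = pd.DataFrame([covariates])
        df = covariates.copy()
        for var in ("cover", "ndvi", "dist_site"):
            if var + "_s" not in df:
                if var not in df:
                    raise ValueError(f"missing covariate {var!r}")
                df[var + "_s"] = self.scaling.transform(df[var].values, var)
        defaults = scenario_frame(scenario or {})
        for col in ("treatment", "tod", "calving", "rut"):
            if col not in df or (scenario is not None and col in scenario):
                df[col] = defaults[col].iloc[0]
        return np.exp(self.linear_predictor(df))


def build_rsf(fit: MixedLogitResults, scaling: Scaler,
              alpha: float = 0.05, enforce_hierarchy: bool = False) -> RSFModel:
    """Formulate an RSF from the significant coefficients of a fitted model."""
    if not fit.converged:
        raise ValueError("refusing to build an RSF from a non-converged fit")
    keep = fit.pvalues < alpha
    if INTERCEPT in keep.index:
        keep[INTERCEPT] = False
    if enforce_hierarchy:
        for name in list(fit.params.index[keep]):
            for comp_term in _parent_columns(name, fit.params.index):
                keep[comp_term] = True
    retained = fit.params[keep]
    if retained.empty:
        raise ValueError("no significant coefficients at alpha="
                         f"{alpha}; cannot build an RSF")
    return RSFModel(coefficients=retained, scaling=scaling, alpha=alpha)


def _parent_columns(name: str, index) -> list[str]:
    comps = name.split(":")
    return [c for c in index
            if c != name and set(c.split(":")) < set(comps)]


def predict_map(model: RSFModel, cover: Raster, ndvi: Raster, sites,
                scenario: dict | None = None) -> Raster:
    """Per-cell RSF scores for one scenario (treatment/time-of-day fixed).

    Distance to sites is measured from cell centers (0 inside a site);
    cells missing either covariate get a missing score.
    """
    if not cover.same_grid(ndvi):
        raise ValueError("cover and NDVI rasters are not co-registered")
    cx, cy = cover.center_grid()
    df = pd.DataFrame({
        "cover": cover.values.ravel(),
        "ndvi": ndvi.values.ravel(),
        "dist_site": distance_to_sites(pd.DataFrame({"x": cx, "y": cy}), sites),
    })
    missing = df["cover"].isna() | df["ndvi"].isna()
    df = df.fillna(0.0)
    scores = model.score(df, scenario)
    scores[missing.to_numpy()] = np.nan
    return Raster(scores.reshape(cover.values.shape), cover.xmin, cover.ymin,
                  cover.cell)


def relative_scores(scores, scenario_ids=None):
    """Scale scores by the median of their scenario (for comparable plots)."""
    s = np.asarray(scores, dtype=float)
    if scenario_ids is None:
        med = np.nanmedian(s)
        if not np.isfinite(med):
            raise ValueError("all scores missing")
        return s / med
    out = np.empty_like(s)
    ids = np.asarray(scenario_ids)
    for sid in np.unique(ids):
        mask = ids == sid
        med = np.nanmedian(s[mask])
        if not np.isfinite(med):
            raise ValueError(f"all scores missing in scenario {sid!r}")
        out[mask] = s[mask] / med
    return out


def score_distance_profile(model: RSFModel, distances_m, scenarios: dict,
                           cover: float | None = None,
                           ndvi: float | None = None) -> pd.DataFrame:
    """Relative RSF score along a distance-to-site gradient, per scenario.

    ``scenarios`` maps scenario id -> context dict (e.g. ``{"before":
    {"treatment": "before", "tod": "day"}}``).  Cover and NDVI are held at
    the dataset mean unless raw values are given.  Scores are scaled by the
    scenario-specific median, so profiles are comparable across scenarios.
    """
    distances = np.asarray(distances_m, dtype=float)
    rows = []
    for sid, ctx in scenarios.items():
        df = pd.DataFrame({"dist_site": distances})
        df["cover_s"] = (0.0 if cover is None
                         else self_scale(model.scaling, "cover", cover))
        df["ndvi_s"] = (0.0 if ndvi is None
                        else self_scale(model.scaling, "ndvi", ndvi))
        w = model.score(df, ctx)
        rel = relative_scores(w)
        for d, r in zip(distances, rel):
            rows.append({"distance_m": d, "scenario": sid, "rel_score": r})
    return pd.DataFrame(rows)


def self_scale(scaling: Scaler, var: str, value: float) -> float:
    return float(scaling.transform(np.array([value]), var)[0])
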