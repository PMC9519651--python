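"""Environmental covariates for used and available points.

Attaches tree cover, NDVI and distance-to-grazing-site to every point,
and manages the centring/scaling applied to continuous predictors before
model fitting.  Scaling parameters are estimated once per dataset (used and
available points pooled) and stored so that map prediction can reuse them
verbatim and so that raw values can be recovered exactly.

Quadratic model terms are squares of the *scaled* variable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely

from .raster import Raster


def ndvi_from_bands(red: Raster, nir: Raster) -> Raster:
    """NDVI = (NIR - red)/(NIR + red), cellwise; 0/0 cells become missing."""
    if not red.same_grid(nir):
        raise ValueError("red and NIR rasters are not co-registered")
    num = nir.values - red.values
    den = nir.values + red.values
    with np.errstate(invalid="ignore", divide="ignore"):
        vals = np.where(den == 0, np.nan, num / den)
    return Raster(vals, red.xmin, red.ymin, red.cell)


def average_rasters(rasters: list[Raster]) -> Raster:
    """Cellwise mean of co-registered rasters, ignoring missing cells."""
    if not rasters:
        raise ValueError("need at least one raster to average")
    first = rasters[0]
    for r in rasters[1:]:
        if not first.same_grid(r):
            raise ValueError("rasters are not co-registered")
    stack = np.stack([r.values for r in rasters])
    with np.errstate(invalid="ignore"):
        vals = np.nanmean(stack, axis=0)
    return Raster(vals, first.xmin, first.ymin, first.cell)


def extract_raster(points: pd.DataFrame, raster: Raster,
                   x_col: str = "x", y_col: str = "y") -> np.ndarray:
    """Nearest-cell raster value at each point (missing outside the extent)."""
    return raster.extract(points[x_col].values, points[y_col].values)


def _site_union(sites):
    polys = list(sites.values()) if isinstance(sites, dict) else list(sites)
    if not polys:
        raise ValueError("need at least one site polygon")
    for p in polys:
        if p is None or p.is_empty or not p.is_valid:
            raise ValueError("invalid site polygon")
    return shapely.union_all(polys)


def distance_to_sites(points: pd.DataFrame, sites,
                      x_col: str = "x", y_col: str = "y") -> np.ndarray:
    """Euclidean distance (m) to the nearest site polygon; 0 inside or on it."""
    union = _site_union(sites)
    pts = shapely.points(points[x_col].values, points[y_col].values)
    return shapely.distance(pts, union)


def point_in_sites(points: pd.DataFrame, sites,
                   x_col: str = "x", y_col: str = "y") -> np.ndarray:
    """1 iff the point lies inside or on the boundary of any site polygon."""
    union = _site_union(sites)
    pts = shapely.points(points[x_col].values, points[y_col].values)
    # covers() includes the boundary, matching dist_site == 0
    return shapely.covers(union, pts).astype(int)


@dataclass
class Scaler:
    """Per-variable centring/scaling with exact inversion.

    ``means``/``sds`` map variable name -> parameter.  ``transform`` returns
    (v - mean)/sd; ``inverse`` undoes it exactly.
    """

    means: dict = field(default_factory=dict)
    sds: dict = field(default_factory=dict)

    @classmethod
    def fit(cls, df: pd.DataFrame, columns) -> "Scaler":
        means, sds = {}, {}
        for col in columns:
            v = np.asarray(df[col], dtype=float)
            v = v[np.isfinite(v)]
            if v.size < 2 or np.nanstd(v) == 0:
                raise ValueError(f"cannot scale constant column {col!r}")
            means[col] = float(np.mean(v))
            sds[col] = float(np.std(v, ddof=1))
        return cls(means, sds)

    def transform(self, values, column: str):
        return (np.asarray(values, dtype=float) - self.means[column]) / self.sds[column]

    def inverse(self, values, column: str):
        return np.asarray(values, dtype=float) * self.sds[column] + self.means[column]

    def to_dict(self) -> dict:
        return {"means": dict(self.means), "sds": dict(self.sds)}

    @classmethod
    def from_dict(cls, d: dict) -> "Scaler":
        return cls(dict(d["means"]), dict(d["sds"]))


def scale_continuous(values) -> tuple[np.ndarray, float, float]:
    """Centre and scale one vector; returns (scaled, mean, sd)."""
    v = np.asarray(values, dtype=float)
    distinct = np.unique(v[np.isfinite(v)])
    if distinct.size < 2:
        raise ValueError("cannot scale a constant (or empty) vector")
    mean = float(np.mean(v[np.isfinite(v)]))
    sd = float(np.std(v[np.isfinite(v)], ddof=1))
    return (v - mean) / sd, mean, sd


CONTINUOUS_VARS = ("cover", "ndvi", "dist_site")


def attach_covariates(points: pd.DataFrame, cover: Raster, ndvi: Raster,
                      sites) -> pd.DataFrame:
    """Add cover, ndvi and dist_site columns to a point table (copy)."""
    out = points.copy()
    out["cover"] = extract_raster(out, cover)
    out["ndvi"] = extract_raster(out, ndvi)
    out["dist_site"] = distance_to_sites(out, sites)
    return out


def add_scaled_columns(points: pd.DataFrame, scaler: Scaler) -> pd.DataFrame:
    """Add ``<var>_s`` scaled columns for every variable the scaler holds."""
    out = points.copy()
    for var in scaler.means:
        out[var + "_s"] = scaler.transform(out[var].values, var)
    return out
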