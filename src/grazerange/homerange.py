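"""Kernel home ranges, isopleths and availability sampling.

Home ranges are fixed-kernel utilisation distributions: a bivariate Gaussian
kernel with a single bandwidth, evaluated on a regular grid (binned KDE:
points are histogrammed onto the grid and smoothed, which at the 20 m default
cell size is indistinguishable from exact evaluation at telemetry scales).
The home range itself is the 0.99 isopleth -- the smallest super-level set of
the density holding 99% of its mass -- chosen deliberately broad so it
captures *available*, not just regularly used, area.

Available points are drawn uniformly from the isopleth polygons and inherit
the timestamp (hence every temporal label) of the used point they are paired
with.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import shapely
from scipy import ndimage
from shapely.geometry import MultiPoint

from .raster import Raster

logger = logging.getLogger(__name__)


class DensitySurface(Raster):
    """A KDE utilisation distribution; integrates to 1 over the grid."""

    def __init__(self, values, xmin, ymin, cell, bandwidth):
        super().__init__(values, xmin, ymin, cell)
        self.bandwidth = float(bandwidth)

    @property
    def total_mass(self) -> float:
        return float(np.nansum(self.values) * self.cell ** 2)


@dataclass
class Isopleth:
    """Super-level-set polygons of a density surface."""

    level: float
    polygons: shapely.Geometry  # (Multi)Polygon
    contained_mass: float

    @property
    def area(self) -> float:
        return self.polygons.area


def reference_bandwidth(x: np.ndarray, y: np.ndarray) -> float:
    """Bivariate reference (Silverman-type) bandwidth: sigma * n^(-1/6).

    sigma is the root mean of the two marginal variances -- the standard
    ad-hoc plug-in for fixed-kernel home ranges.
    """
    n = len(x)
    sigma = np.sqrt(0.5 * (np.var(x, ddof=1) + np.var(y, ddof=1)))
    return float(sigma * n ** (-1.0 / 6.0))


def kde_surface(points: pd.DataFrame, bandwidth="reference",
                cell_m: float = 20.0, pad_bandwidths: float = 3.5,
                x_col: str = "x", y_col: str = "y") -> DensitySurface:
    """Fixed-kernel density surface of relocation points.

    Parameters
    ----------
    points : DataFrame with planar coordinate columns.
    bandwidth : float (meters) or "reference".
    cell_m : grid cell size (m); default 20 to match the covariate rasters.
    pad_bandwidths : grid padding beyond the data extent, in bandwidths.
    """
    x = np.asarray(points[x_col], dtype=float)
    y = np.asarray(points[y_col], dtype=float)
    if len(x) < 5:
        raise ValueError("need at least 5 points for a kernel home range")
    if np.var(x) == 0 and np.var(y) == 0:
        raise ValueError("all points identical; KDE undefined")
    if bandwidth == "reference":
        h = reference_bandwidth(x, y)
    else:
        h = float(bandwidth)
        if h <= 0:
            raise ValueError("bandwidth must be positive")
    if cell_m <= 0:
        raise ValueError("cell size must be positive")

    pad = pad_bandwidths * h
    xmin = np.floor((x.min() - pad) / cell_m) * cell_m
    ymin = np.floor((y.min() - pad) / cell_m) * cell_m
    ncols = int(np.ceil((x.max() + pad - xmin) / cell_m))
    nrows = int(np.ceil((y.max() + pad - ymin) / cell_m))

    hist, _, _ = np.histogram2d(
        y, x, bins=(nrows, ncols),
        range=((ymin, ymin + nrows * cell_m), (xmin, xmin + ncols * cell_m)),
    )
    dens = ndimage.gaussian_filter(hist, sigma=h / cell_m, mode="constant")
    dens /= dens.sum() * cell_m ** 2  # normalise to unit mass
    return DensitySurface(dens, xmin, ymin, cell_m, h)


def isopleth_polygon(surface: DensitySurface, level: float = 0.99) -> Isopleth:
    """Smallest super-level set of the density holding >= ``level`` mass.

    Cells are ranked by density and accumulated until the target mass is
    reached; ties at the threshold density are all included.  The retained
    cell set is polygonised into boundary polygons.
    """
    if not 0.0 < level < 1.0:
        raise ValueError("isopleth level must be in (0, 1)")
    vals = np.nan_to_num(surface.values, nan=0.0)
    if vals.max() <= 0:
        raise ValueError("degenerate density surface")
    flat = vals.ravel()
    order = np.argsort(flat)[::-1]
    cellarea = surface.cell ** 2
    cum = np.cumsum(flat[order]) * cellarea
    k = int(np.searchsorted(cum, level) + 1)
    k = min(k, len(flat))
    threshold = flat[order[k - 1]]
    mask = vals >= threshold  # includes density ties at the threshold
    contained = float(vals[mask].sum() * cellarea)

    rows, cols = np.nonzero(mask)
    xs = surface.xmin + cols * surface.cell
    ys = surface.ymin + rows * surface.cell
    boxes = shapely.box(xs, ys, xs + surface.cell, ys + surface.cell)
    poly = shapely.coverage_union_all(boxes)
    poly = shapely.make_valid(poly)
    return Isopleth(level=level, polygons=poly, contained_mass=contained)


def sample_available(isopleth: Isopleth, used: pd.DataFrame, ratio: int,
                     seed: int, carry_cols=("animal_id", "timestamp",
                                            "sex")) -> pd.DataFrame:
    """Uniform availability sample from the home range, paired with used fixes.

    For each used fix, ``ratio`` points are drawn uniformly from the isopleth
    polygons by rejection sampling from the bounding box.  Each available
    point inherits the timestamp (and the other ``carry_cols``) of its paired
    used fix, gets ``response = 0`` and a ``pair_id`` linking it to that fix.
    """
    if ratio < 1:
        raise ValueError("ratio must be >= 1")
    poly = isopleth.polygons
    if poly.is_empty:
        raise ValueError("empty isopleth")
    rng = np.random.default_rng(seed)
    n_needed = ratio * len(used)
    minx, miny, maxx, maxy = poly.bounds
    accept_frac = poly.area / ((maxx - minx) * (maxy - miny))
    logger.debug("availability rejection sampling, expected acceptance %.3f",
                 accept_frac)
    xs, ys = [], []
    n_have = 0
    while n_have < n_needed:
        m = int((n_needed - n_have) / max(accept_frac, 1e-3) * 1.2) + 64
        cx = rng.uniform(minx, maxx, size=m)
        cy = rng.uniform(miny, maxy, size=m)
        inside = shapely.contains_xy(poly, cx, cy)
        xs.append(cx[inside])
        ys.append(cy[inside])
        n_have += int(inside.sum())
    x = np.concatenate(xs)[:n_needed]
    y = np.concatenate(ys)[:n_needed]

    used = used.reset_index(drop=True)
    rep = np.repeat(np.arange(len(used)), ratio)
    out = pd.DataFrame({"x": x, "y": y, "response": 0})
    for col in carry_cols:
        if col in used:
            out[col] = used[col].to_numpy()[rep]
    out["pair_id"] = rep
    return out


def mcp(points: pd.DataFrame, x_col: str = "x", y_col: str = "y"):
    """Minimum convex polygon (convex hull) of a set of relocations."""
    if len(points) < 3:
        raise ValueError("need at least 3 points for a convex polygon")
    hull = MultiPoint(
        np.column_stack([points[x_col].to_numpy(), points[y_col].to_numpy()])
    ).convex_hull
    if hull.geom_type != "Polygon":
        raise ValueError("degenerate (collinear) point set")
    return hull


def ratio_sensitivity(used: pd.DataFrame, isopleths: dict, attach_fn,
                      fit_fn, ratios, seed: int,
                      tolerance: float = 0.05) -> pd.DataFrame:
    """Stability of RSF coefficients as the use:available ratio grows.

    For each candidate ratio a fresh availability sample is drawn (per
    animal, from its own home range), covariates attached via ``attach_fn``
    and the model fitted by ``fit_fn`` (a callable returning a results object
    with ``params`` and ``bse``).  The report gives, per ratio, the maximum
    SE-scaled coefficient change versus the next ratio, and flags the
    smallest ratio after which every coefficient changes by less than
    ``tolerance``.

    Raises on fitting failure, recording the offending ratio.
    """
    ratios = list(ratios)
    if len(ratios) < 2 or sorted(ratios) != ratios:
        raise ValueError("need >= 2 ratios, sorted ascending")
    fits = {}
    rng = np.random.default_rng(seed)
    for ratio in ratios:
        parts = []
        for animal, sub in used.groupby("animal_id", sort=True):
            avail = sample_available(isopleths[animal], sub, ratio,
                                     seed=int(rng.integers(2 ** 31)))
            parts.append(avail)
        u = used.copy()
        u["response"] = 1
        u["pair_id"] = -1
        data = pd.concat([u] + parts, ignore_index=True)
        data = attach_fn(data)
        try:
            fits[ratio] = fit_fn(data)
        except Exception as exc:  # noqa: BLE001 - annotate and re-raise
            raise RuntimeError(f"fit failed at ratio 1:{ratio}: {exc}") from exc
    rows = []
    for i, ratio in enumerate(ratios):
        row = {"ratio": ratio}
        if i + 1 < len(ratios):
            a, b = fits[ratio], fits[ratios[i + 1]]
            common = a.params.index.intersection(b.params.index)
            scale = a.bse[common].replace(0, np.nan)
            row["max_abs_delta"] = float(
                ((a.params[common] - b.params[common]).abs() / scale).max())
        else:
            row["max_abs_delta"] = np.nan
        rows.append(row)
    table = pd.DataFrame(rows)
    stable = table["max_abs_delta"] < tolerance
    selected = None
    for i in range(len(ratios) - 1):
        if bool(stable.iloc[i:-1].all()):
            selected = ratios[i]
            break
    table.attrs["selected_ratio"] = selected if selected is not None else ratios[-1]
    table.attrs["coefficients"] = {r: fits[r].params for r in ratios}
    return table
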