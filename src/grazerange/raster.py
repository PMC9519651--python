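"""Minimal planar raster grid.

All rasters in this package live in one projected, metric coordinate system.
``Raster`` stores a 2-D value array with row 0 at the *southern* edge (y grows
with row index), a lower-left origin and a square cell size.  Text I/O uses the
ESRI ASCII grid format, which keeps every artifact human-readable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

NODATA = -9999.0


@dataclass
class Raster:
    """A single-band raster on a regular square grid.

    Parameters
    ----------
    values : ndarray, shape (nrows, ncols)
        Cell values; ``values[0, 0]`` is the south-west cell.  NaN marks
        missing cells.
    xmin, ymin : float
        Coordinates (m) of the lower-left corner of the grid.
    cell : float
        Cell edge length in meters; must be positive.
    """

    values: np.ndarray
    xmin: float
    ymin: float
    cell: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("raster values must be 2-D")
        if self.cell <= 0:
            raise ValueError(f"cell size must be positive, got {self.cell}")

    # -- geometry ---------------------------------------------------------
    @property
    def nrows(self) -> int:
        return self.values.shape[0]

    @property
    def ncols(self) -> int:
        return self.values.shape[1]

    @property
    def xmax(self) -> float:
        return self.xmin + self.ncols * self.cell

    @property
    def ymax(self) -> float:
        return self.ymin + self.nrows * self.cell

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Return (xs, ys) 1-D arrays of column / row cell-center coordinates."""
        xs = self.xmin + (np.arange(self.ncols) + 0.5) * self.cell
        ys = self.ymin + (np.arange(self.nrows) + 0.5) * self.cell
        return xs, ys

    def center_grid(self) -> tuple[np.ndarray, np.ndarray]:
        """Flattened x, y coordinates of every cell center (row-major)."""
        xs, ys = self.cell_centers()
        xx, yy = np.meshgrid(xs, ys)
        return xx.ravel(), yy.ravel()

    def same_grid(self, other: "Raster") -> bool:
        return (
            self.values.shape == other.values.shape
            and np.isclose(self.xmin, other.xmin)
            and np.isclose(self.ymin, other.ymin)
            and np.isclose(self.cell, other.cell)
        )

    # -- point extraction -------------------------------------------------
    def index_of(self, x, y):
        """Row/col indices of the cells containing planar points (vectorised)."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        col = np.floor((x - self.xmin) / self.cell).astype(int)
        row = np.floor((y - self.ymin) / self.cell).astype(int)
        return row, col

    def extract(self, x, y):
        """Nearest-cell value for each point; NaN (with count) outside the extent."""
        x = np.atleast_1d(np.asarray(x, dtype=float))
        y = np.atleast_1d(np.asarray(y, dtype=float))
        if self.values.size == 0:
            raise ValueError("cannot extract from an empty raster")
        row, col = self.index_of(x, y)
        inside = (row >= 0) & (row < self.nrows) & (col >= 0) & (col < self.ncols)
        out = np.full(x.shape, np.nan)
        out[inside] = self.values[row[inside], col[inside]]
        n_out = int((~inside).sum())
        if n_out:
            import logging

            logging.getLogger(__name__).warning(
                "%d point(s) outside raster extent -> missing value", n_out
            )
        return out

    # -- text I/O ----------------------------------------------------------
    def write_ascii(self, path) -> None:
        """Write the raster as an ESRI ASCII grid (text)."""
        header = (
            f"ncols {self.ncols}\n"
            f"nrows {self.nrows}\n"
            f"xllcorner {self.xmin!r}\n"
            f"yllcorner {self.ymin!r}\n"
            f"cellsize {self.cell!r}\n"
            f"NODATA_value {NODATA}\n"
        )
        body = np.where(np.isnan(self.values), NODATA, self.values)
        with open(path, "w") as fh:
            fh.write(header)
            # ASCII grids are written north-to-south
            np.savetxt(fh, body[::-1], fmt="%.6g")

    @classmethod
    def read_ascii(cls, path) -> "Raster":
        meta: dict[str, float] = {}
        with open(path) as fh:
            for _ in range(6):
                key, val = fh.readline().split()
                meta[key.lower()] = float(val)
            body = np.loadtxt(fh)
        body = np.atleast_2d(body)[::-1].copy()
        nodata = meta.get("nodata_value", NODATA)
        body[body == nodata] = np.nan
        return cls(body, meta["xllcorner"], meta["yllcorner"], meta["cellsize"])
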