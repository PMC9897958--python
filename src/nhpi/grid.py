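"""Lightweight raster grid container with plain-text (ESRI ASCII) I/O.

All rasters in this package share the convention: row 0 is the northernmost
row, values are cell-centered, coordinates are projected meters. A cell
(row, col) has its center at

    x = xmin + (col + 0.5) * cellsize
    y = ymax - (row + 0.5) * cellsize
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = ["Raster", "read_ascii_grid"]


@dataclass
class Raster:
    """A single-band raster on a regular grid.

    Parameters
    ----------
    values : ndarray, shape (nrows, ncols)
        Cell values; row 0 is the northern edge.
    xmin, ymin : float
        Coordinates of the lower-left corner of the grid (meters).
    cellsize : float
        Cell edge length in meters (default 30 m throughout the package).
    nodata : float
        Sentinel used when writing; NaN cells map to this value.
    """

    values: np.ndarray
    xmin: float
    ymin: float
    cellsize: float = 30.0
    nodata: float = -9999.0

    @property
    def nrows(self) -> int:
        return self.values.shape[0]

    @property
    def ncols(self) -> int:
        return self.values.shape[1]

    @property
    def xmax(self) -> float:
        return self.xmin + self.ncols * self.cellsize

    @property
    def ymax(self) -> float:
        return self.ymin + self.nrows * self.cellsize

    def cell_center(self, row, col):
        """(x, y) coordinates of cell centers (vectorized)."""
        row = np.asarray(row)
        col = np.asarray(col)
        x = self.xmin + (col + 0.5) * self.cellsize
        y = self.ymax - (row + 0.5) * self.cellsize
        return x, y

    def index_of(self, x, y):
        """Nearest-cell (row, col) for point coordinates.

        Points exactly on a cell edge/corner resolve to the northwest-most
        adjoining cell. Raises ValueError for points outside the extent.
        """
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        if np.any(x < self.xmin) or np.any(x > self.xmax) or np.any(
            y < self.ymin
        ) or np.any(y > self.ymax):
            raise ValueError("point(s) outside raster extent")
        fx = (x - self.xmin) / self.cellsize
        fy = (self.ymax - y) / self.cellsize
        col = np.floor(fx).astype(int)
        row = np.floor(fy).astype(int)
        # on a vertical edge -> west cell; on a horizontal edge -> north cell
        on_x_edge = (fx == np.floor(fx)) & (col > 0)
        col = np.where(on_x_edge, col - 1, col)
        on_y_edge = (fy == np.floor(fy)) & (row > 0)
        row = np.where(on_y_edge, row - 1, row)
        col = np.minimum(col, self.ncols - 1)
        row = np.minimum(row, self.nrows - 1)
        return row, col

    def sample(self, x, y):
        """Nearest-cell value lookup at point coordinates."""
        row, col = self.index_of(x, y)
        return self.values[row, col]

    def contains(self, x, y):
        """Boolean mask of points inside the raster extent (inclusive)."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        return (x >= self.xmin) & (x <= self.xmax) & (y >= self.ymin) & (y <= self.ymax)

    def copy_with(self, values: np.ndarray) -> "Raster":
        return Raster(values, self.xmin, self.ymin, self.cellsize, self.nodata)

    def write_ascii(self, path) -> None:
        """Write as an ESRI ASCII grid (plain text)."""
        vals = np.asarray(self.values, dtype=float)
        out = np.where(np.isnan(vals), self.nodata, vals)
        header = (
            f"ncols {self.ncols}\n"
            f"nrows {self.nrows}\n"
            f"xllcorner {self.xmin}\n"
            f"yllcorner {self.ymin}\n"
            f"cellsize {self.cellsize}\n"
            f"NODATA_value {self.nodata}\n"
        )
        with open(path, "w") as fh:
            fh.write(header)
            np.savetxt(fh, out, fmt="%.6g")


def read_ascii_grid(path) -> Raster:
    """Read an ESRI ASCII grid written by :meth:`Raster.write_ascii`."""
    path = Path(path)
    header: dict[str, float] = {}
    with open(path) as fh:
        for _ in range(6):
            key, val = fh.readline().split()
            header[key.lower()] = float(val)
        values = np.loadtxt(fh)
    values = np.atleast_2d(values)
    nodata = header.get("nodata_value", -9999.0)
    values = np.where(values == nodata, np.nan, values)
    return Raster(
        values=values,
        xmin=header["xllcorner"],
        ymin=header["yllcorner"],
        cellsize=header["cellsize"],
        nodata=nodata,
    )
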