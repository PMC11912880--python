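"""Minimal single-band raster container with ESRI ASCII grid I/O.

The environmental layers used here are plain lon/lat (WGS-84) grids; a
raster is an array of cell values plus its georeferencing (lower-left
corner and square cell size in degrees). Row 0 of ``data`` is the
northernmost row, matching the on-disk ESRI ASCII convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

NODATA_DEFAULT = -9999.0


@dataclass
class Raster:
    """A single-band lon/lat raster.

    Parameters
    ----------
    data : 2-D array, row 0 = northernmost row.
    west, south : lower-left corner of the grid, degrees.
    cell_size : square cell edge, degrees.
    nodata : sentinel value for missing cells.
    """

    data: np.ndarray
    west: float
    south: float
    cell_size: float
    nodata: float = NODATA_DEFAULT

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("raster data must be 2-D")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")

    @property
    def n_rows(self) -> int:
        return self.data.shape[0]

    @property
    def n_cols(self) -> int:
        return self.data.shape[1]

    @property
    def east(self) -> float:
        return self.west + self.n_cols * self.cell_size

    @property
    def north(self) -> float:
        return self.south + self.n_rows * self.cell_size

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        """(west, south, east, north)."""
        return (self.west, self.south, self.east, self.north)

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Meshgrid of cell-center coordinates, shaped like ``data``."""
        lon = self.west + (np.arange(self.n_cols) + 0.5) * self.cell_size
        lat = self.north - (np.arange(self.n_rows) + 0.5) * self.cell_size
        return np.meshgrid(lon, lat)

    def sample(self, lons, lats) -> np.ndarray:
        """Nearest-cell values at points; nodata cells return NaN.

        Points outside the raster extent raise ``ValueError``.
        """
        lons = np.atleast_1d(np.asarray(lons, dtype=float))
        lats = np.atleast_1d(np.asarray(lats, dtype=float))
        cols = np.floor((lons - self.west) / self.cell_size).astype(int)
        rows = np.floor((self.north - lats) / self.cell_size).astype(int)
        # points exactly on the east/north edge belong to the last cell
        cols[(lons == self.east)] = self.n_cols - 1
        rows[(lats == self.south)] = self.n_rows - 1
        bad = (cols < 0) | (cols >= self.n_cols) | (rows < 0) | (rows >= self.n_rows)
        if bad.any():
            idx = np.flatnonzero(bad)[:5]
            pts = ", ".join(f"({lons[i]:.5f}, {lats[i]:.5f})" for i in idx)
            raise ValueError(f"{bad.sum()} point(s) outside raster extent, e.g. {pts}")
        vals = self.data[rows, cols].astype(float)
        vals[vals == self.nodata] = np.nan
        return vals

    def to_ascii(self, path) -> None:
        """Write as an ESRI ASCII grid (.asc)."""
        path = Path(path)
        with path.open("w") as fh:
            fh.write(f"ncols {self.n_cols}\n")
            fh.write(f"nrows {self.n_rows}\n")
            fh.write(f"xllcorner {self.west!r}\n")
            fh.write(f"yllcorner {self.south!r}\n")
            fh.write(f"cellsize {self.cell_size!r}\n")
            fh.write(f"NODATA_value {self.nodata!r}\n")
            np.savetxt(fh, self.data, fmt="%.6f")

    @classmethod
    def from_ascii(cls, path) -> "Raster":
        path = Path(path)
        header: dict[str, float] = {}
        with path.open() as fh:
            for _ in range(6):
                key, val = fh.readline().split()
                header[key.lower()] = float(val)
            data = np.loadtxt(fh)
        data = np.atleast_2d(data)
        return cls(
            data=data,
            west=header["xllcorner"],
            south=header["yllcorner"],
            cell_size=header["cellsize"],
            nodata=header.get("nodata_value", NODATA_DEFAULT),
        )
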