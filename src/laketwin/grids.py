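"""Georeferenced raster grids and their on-disk formats.

All grids live in a projected metric coordinate system with y increasing
northwards.  ``origin_xy`` is the map coordinate of the *upper-left corner*
of the upper-left cell; cell extents are half-open ``[x, x + cell_size)``.
Rasters are stored as plain (multi)band float TIFFs with a sidecar JSON file
(`<name>.json`) carrying the grid geometry, the nodata sentinel and, for
multiband scenes, the band wavelengths.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

__all__ = ["GridGeometry", "ElevationGrid", "read_raster", "write_raster"]


@dataclass(frozen=True)
class GridGeometry:
    """Placement of a raster on the map: upper-left corner, cell size, shape."""

    origin_xy: tuple[float, float]
    cell_size: float
    shape: tuple[int, int]

    def __post_init__(self) -> None:
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")
        nrow, ncol = self.shape
        if nrow < 2 or ncol < 2:
            raise ValueError("grid must be at least 2x2")

    def cell_center(self, row, col):
        """Map coordinates of cell centers (vectorized)."""
        x0, y0 = self.origin_xy
        x = x0 + (np.asarray(col) + 0.5) * self.cell_size
        y = y0 - (np.asarray(row) + 0.5) * self.cell_size
        return x, y

    def index_of(self, x: float, y: float) -> tuple[int, int]:
        """Row/col of the cell containing map point (x, y).

        Raises ``IndexError`` for points outside the grid.
        """
        x0, y0 = self.origin_xy
        col = int(np.floor((x - x0) / self.cell_size))
        row = int(np.floor((y0 - y) / self.cell_size))
        nrow, ncol = self.shape
        if not (0 <= row < nrow and 0 <= col < ncol):
            raise IndexError(f"point ({x}, {y}) outside grid")
        return row, col

    def center_mesh(self):
        """(X, Y) arrays of all cell-center coordinates."""
        nrow, ncol = self.shape
        rows, cols = np.mgrid[0:nrow, 0:ncol]
        return self.cell_center(rows, cols)


@dataclass
class ElevationGrid:
    """A single-band elevation raster (DEM or gridded bathymetry)."""

    geometry: GridGeometry
    values: np.ndarray
    nodata: float = float("nan")
    crs_label: str = "local-meters"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != tuple(self.geometry.shape):
            raise ValueError("values shape does not match geometry")

    @property
    def cell_size(self) -> float:
        return self.geometry.cell_size

    def valid_mask(self) -> np.ndarray:
        """True where the cell holds a real elevation."""
        v = self.values
        if np.isnan(self.nodata):
            return np.isfinite(v)
        return np.isfinite(v) & (v != self.nodata)

    def elevation_at(self, x: float, y: float) -> float:
        r, c = self.geometry.index_of(x, y)
        return float(self.values[r, c])


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_raster(path, values, geometry: GridGeometry, nodata=float("nan"),
                 crs_label: str = "local-meters", wavelengths_nm=None) -> None:
    """Write a (multi)band float raster as TIFF + geometry sidecar JSON."""
    path = Path(path)
    arr = np.asarray(values, dtype=np.float32)
    tifffile.imwrite(path, arr, photometric="minisblack")
    meta = {
        "origin_xy": list(geometry.origin_xy),
        "cell_size": geometry.cell_size,
        "shape": list(geometry.shape),
        "nodata": None if np.isnan(nodata) else float(nodata),
        "crs_label": crs_label,
    }
    if wavelengths_nm is not None:
        meta["wavelengths_nm"] = [float(w) for w in wavelengths_nm]
    _sidecar_path(path).write_text(json.dumps(meta, indent=2))


def read_raster(path):
    """Read a raster written by :func:`write_raster`.

    Returns ``(values, geometry, nodata, crs_label, wavelengths_nm)`` where
    wavelengths is ``None`` for single-band rasters without band metadata.
    """
    path = Path(path)
    arr = np.asarray(tifffile.imread(path), dtype=float)
    meta = json.loads(_sidecar_path(path).read_text())
    geometry = GridGeometry(
        origin_xy=tuple(meta["origin_xy"]),
        cell_size=float(meta["cell_size"]),
        shape=tuple(meta["shape"]),
    )
    nodata = meta.get("nodata")
    nodata = float("nan") if nodata is None else float(nodata)
    wavelengths = meta.get("wavelengths_nm")
    return arr, geometry, nodata, meta.get("crs_label", "local-meters"), wavelengths
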