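"""Gridded rasters on a planar km grid.

All spatial layers in the package share one currency: a :class:`GridRaster`,
a rectangular grid of float values with a cell size in kilometres, an origin
at the lower-left corner, and NaN marking masked (no-data) cells.  Row 0 is
the top row; x increases eastward with column index, y increases northward
with decreasing row index.  Cell *centers* carry the coordinates.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field

import numpy as np

__all__ = ["GridRaster", "read_ascii_grid", "write_ascii_grid", "stack_geometry"]


@dataclass
class GridRaster:
    """A single-band raster. ``values`` is a 2-D float array, NaN = masked."""

    values: np.ndarray
    cell_km: float = 1.0
    origin: tuple[float, float] = (0.0, 0.0)  # (x, y) of the lower-left corner

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("raster values must be 2-D")
        if self.cell_km <= 0:
            raise ValueError("cell_km must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def mask(self) -> np.ndarray:
        """Boolean array, True where the cell is valid (unmasked)."""
        return np.isfinite(self.values)

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(x, y) coordinate arrays of every cell center, each of ``shape``."""
        n_rows, n_cols = self.shape
        x0, y0 = self.origin
        xs = x0 + (np.arange(n_cols) + 0.5) * self.cell_km
        ys = y0 + (n_rows - np.arange(n_rows) - 0.5) * self.cell_km
        return np.meshgrid(xs, ys)

    def cell_of(self, x, y) -> tuple[np.ndarray, np.ndarray]:
        """(row, col) indices of the cells containing points (x, y)."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        x0, y0 = self.origin
        n_rows, n_cols = self.shape
        col = np.clip(np.floor((x - x0) / self.cell_km).astype(int), 0, n_cols - 1)
        row = np.clip(
            n_rows - 1 - np.floor((y - y0) / self.cell_km).astype(int), 0, n_rows - 1
        )
        return row, col

    def xy_of(self, row, col) -> tuple[np.ndarray, np.ndarray]:
        """Center coordinates (x, y) of cells at (row, col)."""
        row = np.asarray(row)
        col = np.asarray(col)
        x0, y0 = self.origin
        n_rows = self.shape[0]
        x = x0 + (col + 0.5) * self.cell_km
        y = y0 + (n_rows - row - 0.5) * self.cell_km
        return x, y

    def sample(self, x, y) -> np.ndarray:
        """Raster value at the cell containing each point."""
        row, col = self.cell_of(x, y)
        return self.values[row, col]

    def like(self, values: np.ndarray) -> "GridRaster":
        """A new raster with this geometry and the given values."""
        values = np.asarray(values, dtype=float)
        if values.shape != self.shape:
            raise ValueError("values shape does not match raster geometry")
        return GridRaster(values, cell_km=self.cell_km, origin=self.origin)

    def same_geometry(self, other: "GridRaster") -> bool:
        return (
            self.shape == other.shape
            and np.isclose(self.cell_km, other.cell_km)
            and np.allclose(self.origin, other.origin)
        )


def stack_geometry(rasters: dict[str, GridRaster]) -> GridRaster:
    """Validate that all named rasters share one geometry; return a template.

    Raises ValueError naming the offending layers on mismatch.
    """
    if not rasters:
        raise ValueError("empty raster stack")
    names = list(rasters)
    ref = rasters[names[0]]
    for name in names[1:]:
        if not ref.same_geometry(rasters[name]):
            raise ValueError(
                f"raster geometry mismatch between layers '{names[0]}' and '{name}'"
            )
    return ref


_NODATA = -9999.0


def write_ascii_grid(raster: GridRaster, path) -> None:
    """Write an ESRI ASCII grid (.asc). Masked cells become the nodata value."""
    n_rows, n_cols = raster.shape
    vals = np.where(raster.mask, raster.values, _NODATA)
    header = (
        f"ncols {n_cols}\n"
        f"nrows {n_rows}\n"
        f"xllcorner {raster.origin[0]:.8f}\n"
        f"yllcorner {raster.origin[1]:.8f}\n"
        f"cellsize {raster.cell_km:.8f}\n"
        f"NODATA_value {_NODATA}\n"
    )
    buf = _io.StringIO()
    np.savetxt(buf, vals.astype(np.float32), fmt="%.7g")
    with open(path, "w") as fh:
        fh.write(header)
        fh.write(buf.getvalue())


def read_ascii_grid(path) -> GridRaster:
    """Read an ESRI ASCII grid; the nodata sentinel becomes NaN."""
    header: dict[str, float] = {}
    with open(path) as fh:
        lines = fh.readlines()
    n_header = 0
    for line in lines:
        parts = line.split()
        if len(parts) == 2 and not _is_number(parts[0]):
            header[parts[0].lower()] = float(parts[1])
            n_header += 1
        else:
            break
    required = {"ncols", "nrows", "cellsize"}
    if not required <= set(header):
        raise ValueError(f"ASCII grid header missing {required - set(header)}")
    vals = np.loadtxt(_io.StringIO("".join(lines[n_header:])), ndmin=2)
    if vals.shape != (int(header["nrows"]), int(header["ncols"])):
        raise ValueError("ASCII grid body does not match declared dimensions")
    nodata = header.get("nodata_value", _NODATA)
    vals = np.where(np.isclose(vals, nodata), np.nan, vals)
    if "xllcorner" in header:
        origin = (header["xllcorner"], header["yllcorner"])
    else:  # cell-registered variant
        half = header["cellsize"] / 2.0
        origin = (header["xllcenter"] - half, header["yllcenter"] - half)
    return GridRaster(vals, cell_km=header["cellsize"], origin=origin)


def _is_number(token: str) -> bool:
    try:
        float(token)
        return True
    except ValueError:
        return False
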