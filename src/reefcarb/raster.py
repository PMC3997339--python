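"""Grid and raster containers with plain-text (Esri ASCII grid) I/O.

All rasters in this package are single-band ``float64`` numpy arrays wrapped
in a :class:`Raster` together with a :class:`GridSpec`.  Nodata is represented
in memory as ``NaN``.  The coordinate convention is row-major with the origin
at the upper-left corner; cell centres are at
``x = x0 + (col + 0.5) * cell_size`` and ``y = y0 - (row + 0.5) * cell_size``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = ["GridSpec", "Raster", "read_ascii", "write_ascii"]


@dataclass(frozen=True)
class GridSpec:
    """Shape and georeferencing of a raster grid.

    Parameters
    ----------
    n_rows, n_cols:
        Grid dimensions (must be >= 1).
    cell_size:
        Side length of the square cells in metres (> 0).
    origin:
        (x, y) of the upper-left corner of the grid, metres.
    """

    n_rows: int
    n_cols: int
    cell_size: float = 1.0
    origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError(
                f"grid dimensions must be >= 1, got {self.n_rows}x{self.n_cols}"
            )
        if not self.cell_size > 0:
            raise ValueError(f"cell_size must be > 0, got {self.cell_size}")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    @property
    def cell_area(self) -> float:
        """Planar area of one cell, m^2."""
        return self.cell_size**2

    @property
    def extent(self) -> tuple[float, float]:
        """(width, height) of the grid in metres."""
        return (self.n_cols * self.cell_size, self.n_rows * self.cell_size)

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Return (x, y) coordinate arrays of shape (n_rows, n_cols)."""
        x0, y0 = self.origin
        xs = x0 + (np.arange(self.n_cols) + 0.5) * self.cell_size
        ys = y0 - (np.arange(self.n_rows) + 0.5) * self.cell_size
        return np.meshgrid(xs, ys)

    def cell_containing(self, x: float, y: float) -> tuple[int, int]:
        """(row, col) of the cell containing point (x, y)."""
        x0, y0 = self.origin
        col = int(np.floor((x - x0) / self.cell_size))
        row = int(np.floor((y0 - y) / self.cell_size))
        if not (0 <= row < self.n_rows and 0 <= col < self.n_cols):
            raise ValueError(f"point ({x}, {y}) falls outside the grid")
        return row, col


@dataclass
class Raster:
    """A single-band raster: float64 values (NaN = nodata) on a GridSpec."""

    values: np.ndarray
    grid: GridSpec

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.grid.shape:
            raise ValueError(
                f"values shape {self.values.shape} does not match grid "
                f"{self.grid.shape}"
            )

    @classmethod
    def from_array(
        cls,
        values: np.ndarray,
        cell_size: float = 1.0,
        origin: tuple[float, float] = (0.0, 0.0),
    ) -> "Raster":
        values = np.asarray(values, dtype=float)
        if values.ndim != 2:
            raise ValueError("raster values must be 2-D")
        return cls(values, GridSpec(values.shape[0], values.shape[1], cell_size, origin))

    @classmethod
    def full_like(cls, other: "Raster", fill: float = np.nan) -> "Raster":
        return cls(np.full(other.grid.shape, fill, dtype=float), other.grid)

    def copy(self) -> "Raster":
        return Raster(self.values.copy(), self.grid)

    @property
    def valid_mask(self) -> np.ndarray:
        return np.isfinite(self.values)

    def value_at(self, x: float, y: float) -> float:
        """Nearest-cell lookup (the value of the cell containing the point)."""
        row, col = self.grid.cell_containing(x, y)
        return float(self.values[row, col])

    def same_grid(self, other: "Raster") -> bool:
        return self.grid == other.grid


def require_coregistered(**rasters: Raster) -> GridSpec:
    """Check that all rasters share one GridSpec; return it."""
    items = list(rasters.items())
    name0, first = items[0]
    for name, r in items[1:]:
        if r.grid != first.grid:
            raise ValueError(
                f"raster '{name}' is not co-registered with '{name0}': "
                f"{r.grid} != {first.grid}"
            )
    return first.grid


def write_ascii(raster: Raster, path: str | Path, nodata: float = -9999.0) -> None:
    """Write a raster as an Esri ASCII grid (text) file."""
    path = Path(path)
    g = raster.grid
    x0, y0 = g.origin
    yll = y0 - g.n_rows * g.cell_size
    vals = np.where(np.isfinite(raster.values), raster.values, nodata)
    header = (
        f"ncols {g.n_cols}\n"
        f"nrows {g.n_rows}\n"
        f"xllcorner {x0!r}\n"
        f"yllcorner {yll!r}\n"
        f"cellsize {g.cell_size!r}\n"
        f"NODATA_value {nodata!r}\n"
    )
    with path.open("w") as fh:
        fh.write(header)
        np.savetxt(fh, vals, fmt="%.10g")


def read_ascii(path: str | Path) -> Raster:
    """Read an Esri ASCII grid written by :func:`write_ascii`."""
    path = Path(path)
    header: dict[str, float] = {}
    with path.open() as fh:
        for _ in range(6):
            key, val = fh.readline().split()
            header[key.lower()] = float(val)
        vals = np.loadtxt(fh, ndmin=2)
    n_rows, n_cols = int(header["nrows"]), int(header["ncols"])
    cell = header["cellsize"]
    origin = (header["xllcorner"], header["yllcorner"] + n_rows * cell)
    nodata = header["nodata_value"]
    vals = np.where(vals == nodata, np.nan, vals)
    return Raster(vals, GridSpec(n_rows, n_cols, cell, origin))
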