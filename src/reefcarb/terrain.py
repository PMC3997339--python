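"""Physical covariates of the reef surface: slope, rugosity, band-ratio depth.

Rugosity here is the ratio of true (triangulated) three-dimensional surface
area to planar area within a moving window, computed with the eight-triangle
tessellation around each cell centre (Jenness-style).  For a plane tilted at
angle theta the ratio is exactly 1/cos(theta); for a flat surface it is
exactly 1.  Cells whose window is incomplete (grid edge or adjacent nodata)
are set to nodata rather than computed from a shrunken window.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .raster import Raster, require_coregistered

__all__ = ["BathymetryParams", "derive_slope", "derive_rugosity", "band_ratio_depth"]

# the 8 neighbours ordered clockwise so consecutive pairs are adjacent
_NEIGHBOUR_OFFSETS = [
    (-1, -1), (-1, 0), (-1, 1), (0, 1),
    (1, 1), (1, 0), (1, -1), (0, -1),
]


@dataclass(frozen=True)
class BathymetryParams:
    """Coefficients of the log band-ratio depth model.

    depth = m1 * ln(n_scale * b1) / ln(n_scale * b2) - m0
    """

    m0: float = 55.0
    m1: float = 60.0
    n_scale: float = 1000.0

    def __post_init__(self) -> None:
        if not self.n_scale > 0:
            raise ValueError(f"n_scale must be > 0, got {self.n_scale}")


def derive_slope(dem: Raster) -> Raster:
    """Slope in degrees from central differences of the DEM.

    Border cells (and cells with any nodata neighbour entering the stencil)
    are nodata.  Requires at least a 3x3 grid of valid cells.
    """
    z = dem.values
    if z.shape[0] < 3 or z.shape[1] < 3:
        raise ValueError("slope requires a DEM of at least 3x3 cells")
    if not np.isfinite(z).any():
        raise ValueError("slope of an all-nodata DEM is undefined")
    c = dem.grid.cell_size
    out = np.full_like(z, np.nan)
    gx = (z[1:-1, 2:] - z[1:-1, :-2]) / (2.0 * c)
    gy = (z[2:, 1:-1] - z[:-2, 1:-1]) / (2.0 * c)
    out[1:-1, 1:-1] = np.degrees(np.arctan(np.hypot(gx, gy)))
    return Raster(out, dem.grid)


def _cell_surface_area(z: np.ndarray, cell_size: float) -> np.ndarray:
    """Triangulated 3-D surface area of each cell (NaN where incomplete).

    Eight triangles join the cell centre to the midpoints of the segments
    towards its eight neighbours; their projections tile the cell exactly, so
    a tilted plane yields cell_area / cos(theta).
    """
    c = cell_size
    padded = np.pad(z, 1, constant_values=np.nan)
    centre = z
    mids = []  # midpoint (dx, dy, z) towards each neighbour
    for di, dj in _NEIGHBOUR_OFFSETS:
        nb = padded[1 + di : 1 + di + z.shape[0], 1 + dj : 1 + dj + z.shape[1]]
        mids.append((0.5 * dj * c, -0.5 * di * c, 0.5 * (nb + centre)))
    area = np.zeros_like(z)
    for a in range(8):
        b = (a + 1) % 8
        ax, ay, az = mids[a]
        bx, by, bz = mids[b]
        # triangle (centre, mid_a, mid_b); centre is local origin at height z
        la = np.sqrt(ax**2 + ay**2 + (az - centre) ** 2)
        lb = np.sqrt(bx**2 + by**2 + (bz - centre) ** 2)
        lo = np.sqrt((ax - bx) ** 2 + (ay - by) ** 2 + (az - bz) ** 2)
        s = 0.5 * (la + lb + lo)
        area += np.sqrt(np.maximum(s * (s - la) * (s - lb) * (s - lo), 0.0))
    return area


def derive_rugosity(dem: Raster, window: int = 3) -> Raster:
    """Rugosity (3-D surface area / planar area) in a moving window.

    Parameters
    ----------
    dem:
        Depth or elevation raster; rugosity is invariant to the sign
        convention and to adding a constant.
    window:
        Odd window size in cells, >= 3.  The ratio is the summed triangulated
        surface area of the cells in the window over the window's planar
        area.  Values are >= 1 by construction.
    """
    if window < 3 or window % 2 == 0:
        raise ValueError(f"window must be odd and >= 3, got {window}")
    z = dem.values
    if window > min(z.shape):
        raise ValueError(
            f"window {window} larger than grid {z.shape[0]}x{z.shape[1]}"
        )
    c = dem.grid.cell_size
    cell_area = _cell_surface_area(z, c)
    half = window // 2
    out = np.full_like(z, np.nan)
    # sliding-window sum; any NaN cell area (edges / nodata) propagates
    view = np.lib.stride_tricks.sliding_window_view(cell_area, (window, window))
    sums = view.sum(axis=(2, 3))
    out[half:-half or None, half:-half or None] = sums / (window**2 * c**2)
    # guard against round-off marginally below 1 on perfectly flat surfaces
    out = np.where(np.isfinite(out), np.maximum(out, 1.0), np.nan)
    return Raster(out, dem.grid)


def band_ratio_depth(b1: Raster, b2: Raster, params: BathymetryParams) -> Raster:
    """Depth from the log band-ratio of two reflectance rasters.

    depth = m1 * ln(n * b1) / ln(n * b2) - m0, per cell.  Cells where either
    band is non-positive or where the denominator log vanishes become nodata.
    """
    grid = require_coregistered(b1=b1, b2=b2)
    n = params.n_scale
    with np.errstate(invalid="ignore", divide="ignore"):
        num = np.log(np.where(b1.values > 0, n * b1.values, np.nan))
        den = np.log(np.where(b2.values > 0, n * b2.values, np.nan))
        den = np.where(den == 0.0, np.nan, den)
        depth = params.m1 * num / den - params.m0
    return Raster(depth, grid)
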