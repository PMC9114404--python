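"""Terrain derivatives of a bathymetry grid: slope, aspect, BPI.

Slope and aspect follow Horn's 3x3 finite-difference gradient, the
default of common raster tooling.  Depth is stored positive-down, so the
operators work on elevation (negative depth) internally; the sign only
matters for aspect and BPI, whose conventions are documented per
function.  The bathymetric position index (BPI) compares each cell with
the mean of a surrounding disc, so positive values flag local highs
(seamounts, hills) and negative values local lows (troughs, moats).
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .grids import Grid, GridStack


def _horn_gradient(depth: Grid):
    """Elevation gradient (east, north components) by Horn's method.

    Returns (gx, gy) in m/m; NaN at boundary cells and wherever any of
    the nine neighbourhood cells is nodata.
    """
    if depth.nrows < 3 or depth.ncols < 3:
        raise ValueError("slope/aspect need at least a 3x3 grid")
    z = -depth.values  # elevation
    cell = depth.cell_size_m
    nw, n_, ne = z[:-2, :-2], z[:-2, 1:-1], z[:-2, 2:]
    w_, e_ = z[1:-1, :-2], z[1:-1, 2:]
    sw, s_, se = z[2:, :-2], z[2:, 1:-1], z[2:, 2:]
    gx = ((ne + 2 * e_ + se) - (nw + 2 * w_ + sw)) / (8 * cell)
    # row index grows southwards, so the "north" rows are the low indices
    gy = ((nw + 2 * n_ + ne) - (sw + 2 * s_ + se)) / (8 * cell)
    full_gx = np.full(z.shape, np.nan)
    full_gy = np.full(z.shape, np.nan)
    full_gx[1:-1, 1:-1] = gx
    full_gy[1:-1, 1:-1] = gy
    bad = ~np.isfinite(full_gx) | ~np.isfinite(full_gy)
    full_gx[bad] = np.nan
    full_gy[bad] = np.nan
    return full_gx, full_gy


def slope(depth: Grid) -> Grid:
    """Slope in degrees, in [0, 90]; nodata at boundary/nodata-adjacent cells."""
    gx, gy = _horn_gradient(depth)
    out = np.degrees(np.arctan(np.hypot(gx, gy)))
    return depth.copy(values=out, name="slope_deg", units="deg")


def aspect(depth: Grid):
    """Downslope azimuth as its (sin, cos) pair.

    Azimuth is measured clockwise from north toward the direction of
    steepest descent.  Flat cells (zero gradient) return the marker pair
    (0, 0), which keeps the layers defined everywhere without inventing a
    direction; consumers treat aspect as this circular pair, never as raw
    degrees, to avoid the 0/360 discontinuity.
    """
    gx, gy = _horn_gradient(depth)
    de, dn = -gx, -gy  # steepest-descent vector (east, north)
    az = np.arctan2(de, dn)
    sin_a, cos_a = np.sin(az), np.cos(az)
    flat = np.isfinite(gx) & (gx == 0) & (gy == 0)
    sin_a[flat] = 0.0
    cos_a[flat] = 0.0
    return (
        depth.copy(values=sin_a, name="aspect_sin", units=""),
        depth.copy(values=cos_a, name="aspect_cos", units=""),
    )


def _disc_kernel(radius_cells: float) -> np.ndarray:
    r = int(np.floor(radius_cells))
    di, dj = np.meshgrid(np.arange(-r, r + 1), np.arange(-r, r + 1), indexing="ij")
    kernel = (di ** 2 + dj ** 2) <= radius_cells ** 2 + 1e-9
    kernel[r, r] = False  # centre excluded
    return kernel.astype(float)


def bpi(depth: Grid, radius_m: float, inner_radius_m: float = 0.0) -> Grid:
    """Bathymetric position index at the given neighbourhood scale.

    BPI = elevation(cell) - mean elevation over valid cells within a disc
    of ``radius_m`` around it (centre excluded); in metres, positive on
    local highs.  ``inner_radius_m`` > 0 turns the disc into an annulus
    for sensitivity checks.  Radii are converted to cells by rounding
    ``radius_m / cell_size_m`` to the nearest integer >= 1.
    """
    if radius_m < depth.cell_size_m:
        raise ValueError("bpi radius must be at least one cell")
    r_cells = max(1, round(radius_m / depth.cell_size_m))
    kernel = _disc_kernel(r_cells)
    if inner_radius_m > 0:
        inner = _disc_kernel(inner_radius_m / depth.cell_size_m)
        pad = (kernel.shape[0] - inner.shape[0]) // 2
        if pad >= 0:
            kernel[pad:kernel.shape[0] - pad, pad:kernel.shape[0] - pad] -= inner
            kernel = np.clip(kernel, 0, 1)
    z = -depth.values
    valid = np.isfinite(z)
    zfill = np.where(valid, z, 0.0)
    neigh_sum = ndimage.convolve(zfill, kernel, mode="constant", cval=0.0)
    neigh_n = ndimage.convolve(valid.astype(float), kernel, mode="constant", cval=0.0)
    out = np.full(z.shape, np.nan)
    ok = valid & (neigh_n > 0.5)
    out[ok] = z[ok] - neigh_sum[ok] / neigh_n[ok]
    return depth.copy(values=out, name=f"bpi_{int(radius_m)}", units="m")


def terrain_stack(depth: Grid, bpi_radii_m=(1000.0, 17000.0),
                  include_depth: bool = True) -> GridStack:
    """Bundle depth with slope, aspect pair, and BPI at each radius."""
    stack = GridStack()
    if include_depth:
        stack.add("depth", depth.copy())
    stack.add("slope_deg", slope(depth))
    sin_a, cos_a = aspect(depth)
    stack.add("aspect_sin", sin_a)
    stack.add("aspect_cos", cos_a)
    for r in bpi_radii_m:
        stack.add(f"bpi_{int(r)}", bpi(depth, r))
    return stack
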