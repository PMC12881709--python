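"""Engineered landscape covariates.

Derivations used to build the model's explanatory layers from raw rasters and
feature locations: Gaussian-kernel habitat connectivity, distance-to-nearest-
feature surfaces, per-cell habitat area and edge length aggregated from a
finer binary map, and z-standardization (in :mod:`pestscape.grids`).

All distances are planar centre-to-centre kilometres.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .grids import GridSpec, Raster


def gaussian_kernel_2d(cell_km: float, sigma_km: float,
                       truncation_sigmas: float = 3.0) -> np.ndarray:
    """Radially truncated, normalized 2-D Gaussian distance kernel.

    Weight of a cell at centre distance ``d``: ``exp(-d^2 / (2 sigma^2))``,
    zero beyond ``truncation_sigmas * sigma``, normalized to sum to one.
    """
    if sigma_km <= 0:
        raise ValueError("sigma_km must be positive")
    radius = int(math.ceil(truncation_sigmas * sigma_km / cell_km))
    offs = np.arange(-radius, radius + 1) * cell_km
    dx, dy = np.meshgrid(offs, offs)
    d2 = dx**2 + dy**2
    w = np.exp(-d2 / (2.0 * sigma_km**2))
    w[np.sqrt(d2) > truncation_sigmas * sigma_km] = 0.0
    return w / w.sum()


def gaussian_connectivity(x: Raster, sigma_km: float = 3.0,
                          truncation_sigmas: float = 3.0) -> Raster:
    """Connectivity layer: Gaussian-weighted sum of a habitat layer.

    Each output cell is the kernel-weighted average of the input over the
    surrounding cells, quantifying the density of habitat around the focal
    cell. Near the domain edge (and around missing cells) the kernel is
    renormalized over its in-domain support, so a constant layer maps to
    itself everywhere.
    """
    kern = gaussian_kernel_2d(x.grid.cell_km, sigma_km, truncation_sigmas)
    vals = x.values
    mask = np.isfinite(vals).astype(float)
    filled = np.where(mask > 0, vals, 0.0)
    num = ndimage.convolve(filled, kern, mode="constant", cval=0.0)
    den = ndimage.convolve(mask, kern, mode="constant", cval=0.0)
    out = np.where(den > 0, num / np.where(den > 0, den, 1.0), np.nan)
    out[mask == 0] = np.nan
    return x.copy_with(out, name=f"{x.name}_connectivity" if x.name else "connectivity")


def gaussian_profile_fraction(radius_km: float, sigma_km: float = 3.0) -> float:
    """Fraction of a 1-D Gaussian distance profile within ``±radius_km``.

    The conventional reading of kernel reach: with sd 3 km, 68.3% of the
    one-dimensional weight lies within ±3 km of the focal cell and 99.7%
    within ±9 km.
    """
    if sigma_km <= 0:
        raise ValueError("sigma_km must be positive")
    return math.erf(radius_km / (sigma_km * math.sqrt(2.0)))


def distance_to_nearest(grid: GridSpec, features: np.ndarray) -> Raster:
    """Per-cell Euclidean distance (km) from cell centre to the nearest feature.

    Used for distance-to-border-control-post and distance-to-park/garden
    style layers. A feature exactly at a cell centre gives that cell 0.
    """
    features = np.atleast_2d(np.asarray(features, dtype=float))
    if features.size == 0:
        raise ValueError("need at least one feature location")
    tree = cKDTree(features)
    d, _ = tree.query(grid.center_points())
    return Raster(grid, d.reshape(grid.shape), name="distance", units="km")


def area_edge_per_cell(fine_binary: Raster, coarse: GridSpec) -> tuple[Raster, Raster]:
    """Habitat area (km²) and internal edge length (km) per coarse cell.

    ``fine_binary`` is a 0/1 habitat map on a finer grid whose resolution
    divides the coarse resolution and whose extent matches. Area is the
    habitat fraction times the coarse cell area. Edge length counts the
    sides shared by a habitat and a non-habitat fine cell, restricted to
    sides lying strictly inside a coarse cell (sides on coarse-cell
    boundaries belong to no single cell and are excluded).
    """
    vals = fine_binary.values
    if not np.isin(vals[np.isfinite(vals)], (0.0, 1.0)).all():
        raise ValueError("fine raster must be binary (0/1)")
    f = fine_binary.grid.cell_km
    ratio = coarse.cell_km / f
    if abs(ratio - round(ratio)) > 1e-9:
        raise ValueError("fine resolution must divide coarse resolution")
    r = int(round(ratio))
    if fine_binary.grid.nrows != coarse.nrows * r or fine_binary.grid.ncols != coarse.ncols * r:
        raise ValueError("fine and coarse grids must cover the same extent")

    b = np.nan_to_num(vals)
    area = b.reshape(coarse.nrows, r, coarse.ncols, r).sum(axis=(1, 3)) * f**2

    edge = np.zeros(coarse.shape)
    # Vertical neighbours (share a horizontal side); side interior to a
    # coarse cell iff both fine rows fall in the same coarse row.
    dv = np.abs(np.diff(b, axis=0))  # (nf-1, nf_cols)
    rows = np.arange(dv.shape[0])
    keep = (rows + 1) % r != 0
    dv = dv[keep]
    crow = (rows[keep] // r)
    for i, cr in enumerate(crow):
        seg = dv[i].reshape(coarse.ncols, r).sum(axis=1) * f
        edge[cr] += seg
    # Horizontal neighbours (share a vertical side).
    dh = np.abs(np.diff(b, axis=1))  # (nf_rows, nf-1)
    cols = np.arange(dh.shape[1])
    keep = (cols + 1) % r != 0
    dh = dh[:, keep]
    ccol = (cols[keep] // r)
    sums = dh.reshape(coarse.nrows, r, dh.shape[1]).sum(axis=1) * f
    for j, cc in enumerate(ccol):
        edge[:, cc] += sums[:, j]

    name = fine_binary.name or "habitat"
    return (
        Raster(coarse, area, name=f"{name}_area", units="km2"),
        Raster(coarse, edge, name=f"{name}_edge", units="km"),
    )
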