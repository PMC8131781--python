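"""Landscape covariates: focal statistics, patch metrics, aspect, distances.

These operators build the habitat-composition and dispersal covariates of
the regional niche models: percentage of forest and mean basal area within
a 1 km radius, host cover within 10 km (a flight-distance ceiling for the
moth), habitat fragmentation and heterogeneity per km² block, aspect
quadrants from the DEM, and minimum-distance surfaces to prior-year
observations.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree
from skimage.measure import label as cc_label

from .raster import GridRaster

__all__ = [
    "focal_mean",
    "focal_percentage",
    "patch_metrics",
    "min_distance_map",
    "aspect_category",
    "ASPECT_CODES",
]

# aspect encoding: 0 = flat/undefined, then compass quadrants
ASPECT_CODES = {0: "flat", 1: "N", 2: "E", 3: "S", 4: "W"}


def _disk_footprint(radius_km: float, cell_km: float) -> np.ndarray:
    """Boolean window of cells whose center lies within radius of the focus."""
    r_cells = radius_km / cell_km
    k = int(np.floor(r_cells))
    if k < 1:
        return np.ones((1, 1), dtype=bool)
    dy, dx = np.mgrid[-k : k + 1, -k : k + 1]
    return (dx**2 + dy**2) <= r_cells**2 + 1e-9


def focal_mean(raster: GridRaster, radius_km: float) -> GridRaster:
    """Mean of the input over a circular window around each cell.

    The window covers cells whose centers lie within ``radius_km`` of the
    focal cell center.  Masked cells are excluded from both numerator and
    denominator; near borders the window simply shrinks (no padding), so
    edge means stay unbiased.  A radius below half a cell returns the input.
    """
    if radius_km < 0:
        raise ValueError("radius_km must be >= 0")
    foot = _disk_footprint(radius_km, raster.cell_km).astype(float)
    valid = raster.mask.astype(float)
    vals = np.where(raster.mask, raster.values, 0.0)
    num = ndimage.convolve(vals, foot, mode="constant", cval=0.0)
    den = ndimage.convolve(valid, foot, mode="constant", cval=0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(den > 0, num / den, np.nan)
    return raster.like(out)


def focal_percentage(raster: GridRaster, radius_km: float) -> GridRaster:
    """``focal_mean`` scaled to percent — for binary or fraction rasters."""
    mean = focal_mean(raster, radius_km)
    return raster.like(mean.values * 100.0)


def patch_metrics(
    habitat: GridRaster, block_km: float = 1.0, connectivity: int = 1
) -> tuple[GridRaster, GridRaster]:
    """Fragmentation and heterogeneity per km² block of the habitat map.

    For every block of ``block_km`` × ``block_km`` (anchored at the raster
    origin; partial edge blocks use their available cells): P = number of
    connected same-class patches (4-connectivity by default), C = number of
    distinct classes.  Fragmentation = P / C, heterogeneity = P × C; both
    are broadcast back to the cells of the block.  Fully masked blocks are
    NaN.
    """
    n_rows, n_cols = habitat.shape
    cells_per_block = max(int(round(block_km / habitat.cell_km)), 1)
    frag = np.full((n_rows, n_cols), np.nan)
    het = np.full((n_rows, n_cols), np.nan)
    for r0 in range(0, n_rows, cells_per_block):
        for c0 in range(0, n_cols, cells_per_block):
            block = habitat.values[r0 : r0 + cells_per_block, c0 : c0 + cells_per_block]
            valid = np.isfinite(block)
            if not valid.any():
                continue
            classes = np.unique(block[valid]).astype(int)
            n_patches = 0
            for cls in classes:
                n_patches += cc_label(
                    (block == cls).astype(int), connectivity=connectivity
                ).max()
            c = len(classes)
            frag[r0 : r0 + cells_per_block, c0 : c0 + cells_per_block] = n_patches / c
            het[r0 : r0 + cells_per_block, c0 : c0 + cells_per_block] = n_patches * c
    return habitat.like(frag), habitat.like(het)


def min_distance_map(
    points: pd.DataFrame,
    grid: GridRaster,
    subset_rule=None,
    units: str = "km",
) -> GridRaster:
    """Euclidean distance from every cell center to the nearest point.

    ``subset_rule`` is an optional boolean predicate on the point table
    (e.g. ``lambda df: df.severity >= 3`` for high-severity observations
    only).  ``units`` is 'km' (internal) or 'm' (reporting convention).
    """
    retained = points
    rule_name = "all records"
    if subset_rule is not None:
        keep = subset_rule(points)
        retained = points.loc[np.asarray(keep, dtype=bool)]
        rule_name = getattr(subset_rule, "__name__", "subset rule")
    if len(retained) == 0:
        raise ValueError(f"no points retained after subset rule ({rule_name})")
    tree = cKDTree(retained[["x", "y"]].to_numpy(dtype=float))
    cx, cy = grid.cell_centers()
    dist, _ = tree.query(np.column_stack([cx.ravel(), cy.ravel()]))
    dist = dist.reshape(grid.shape)
    if units == "m":
        dist = dist * 1000.0
    elif units != "km":
        raise ValueError("units must be 'km' or 'm'")
    return grid.like(dist)


def aspect_category(dem: GridRaster, flat_tolerance: float = 1e-6) -> GridRaster:
    """Down-slope facing quadrant per cell, from central differences.

    Codes: 1=N (315°–45°), 2=E (45°–135°), 3=S (135°–225°), 4=W
    (225°–315°), 0=flat where the gradient magnitude is below
    ``flat_tolerance``.  A constant DEM is therefore all flat.  Bearings
    are measured clockwise from north of the *down-slope* vector (the
    standard DEM aspect convention).
    """
    z = dem.values
    # np.gradient axis 0 runs down rows = southward; axis 1 eastward
    dz_drow, dz_dcol = np.gradient(z, dem.cell_km)
    dz_dnorth = -dz_drow
    dz_deast = dz_dcol
    down_e, down_n = -dz_deast, -dz_dnorth
    mag = np.hypot(down_e, down_n)
    bearing = np.degrees(np.arctan2(down_e, down_n)) % 360.0
    cat = np.ones(z.shape)  # default N
    cat[(bearing >= 45) & (bearing < 135)] = 2
    cat[(bearing >= 135) & (bearing < 225)] = 3
    cat[(bearing >= 225) & (bearing < 315)] = 4
    cat[mag < flat_tolerance] = 0
    cat[~np.isfinite(z)] = np.nan
    return dem.like(cat)
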