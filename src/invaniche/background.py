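"""Background samples and native-model-informed background weights.

An invader is not in equilibrium with its new range: climatically suitable
cells it simply has not reached yet end up in the background sample as
"false absences" and bias the fitted niche narrow.  The remedy implemented
here weights each invaded-range background point by how *unsuitable* the
native-range model judges it:

    w(p) = 1 / (1 + (p / (1 − p))²),     p = native-model suitability,

so points the native model calls suitable (likely false absences) count
for little, while points it agrees are poor habitat (likely true absences)
keep full weight.  w decreases strictly from w(0) = 1 to w(1) = 0, with
w(½) = ½.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .raster import GridRaster

__all__ = [
    "sample_background",
    "buffered_background",
    "gallien_weight",
    "weight_background",
]


def _sample_cells(
    template: GridRaster, valid: np.ndarray, n: int, rng: np.random.Generator
) -> pd.DataFrame:
    idx = np.flatnonzero(valid.ravel())
    if idx.size == 0:
        raise ValueError("background mask has no valid cells")
    if n <= idx.size:
        chosen = rng.choice(idx, size=n, replace=False)
    else:  # more points than cells: sample with replacement
        chosen = rng.choice(idx, size=n, replace=True)
    rows, cols = np.unravel_index(chosen, template.shape)
    x, y = template.xy_of(rows, cols)
    return pd.DataFrame({"x": x, "y": y})


def sample_background(
    template: GridRaster,
    n: int = 10000,
    seed: int = 0,
    valid: np.ndarray | None = None,
) -> pd.DataFrame:
    """Uniform random background points over the valid cells of a raster.

    ``valid`` optionally restricts the support (boolean array on the grid);
    by default every unmasked cell qualifies.  Points are cell centers,
    drawn without replacement while ``n`` does not exceed the number of
    valid cells.
    """
    if valid is None:
        valid = template.mask
    return _sample_cells(template, np.asarray(valid, dtype=bool), n, np.random.default_rng(seed))


def buffered_background(
    presences: pd.DataFrame,
    template: GridRaster,
    buffer_km: float = 10.0,
    n: int = 10000,
    seed: int = 0,
    host_mask: np.ndarray | None = None,
) -> pd.DataFrame:
    """Background restricted to a buffer around presences, optionally
    host-masked.

    Valid cells lie within ``buffer_km`` of at least one presence (the
    union of disks) and, when ``host_mask`` is given, inside the host
    distribution.  This construction removes the distance-to-observation
    signal (every background point is near a presence) and, with the mask,
    the host-cover signal, isolating the remaining covariates.
    """
    if len(presences) == 0:
        raise ValueError("presence set is empty")
    tree = cKDTree(presences[["x", "y"]].to_numpy(dtype=float))
    cx, cy = template.cell_centers()
    dist, _ = tree.query(np.column_stack([cx.ravel(), cy.ravel()]))
    valid = (dist.reshape(template.shape) <= buffer_km + 1e-9) & template.mask
    if host_mask is not None:
        valid &= np.asarray(host_mask, dtype=bool)
    if not valid.any():
        raise ValueError("buffer ∩ host mask contains no valid cells")
    return _sample_cells(template, valid, n, np.random.default_rng(seed))


def gallien_weight(p) -> np.ndarray:
    """Background weight from native-model suitability p ∈ [0, 1].

    w(p) = 1 / (1 + (p/(1−p))²); w(1) = 0 by continuity.  Strictly
    decreasing: high native suitability ⇒ likely false absence ⇒ low
    weight.
    """
    p_arr = np.asarray(p, dtype=float)
    if np.any((p_arr < 0) | (p_arr > 1) | ~np.isfinite(p_arr)):
        raise ValueError("native suitability values must lie in [0, 1]")
    with np.errstate(divide="ignore"):
        odds = np.where(p_arr < 1.0, p_arr / (1.0 - p_arr), np.inf)
    w = np.where(np.isinf(odds), 0.0, 1.0 / (1.0 + odds**2))
    if np.isscalar(p) or np.ndim(p) == 0:
        return float(w)
    return w


def weight_background(
    background_covariates: pd.DataFrame, native_model
) -> pd.DataFrame:
    """Attach the native-projection value p and its weight to each point.

    Returns a copy of the table with columns ``p`` (native-model
    suitability at the point) and ``weight``.  Presences are never
    weighted — only background rows pass through here.
    """
    p = native_model.predict(background_covariates)
    out = background_covariates.copy()
    out["p"] = p
    out["weight"] = gallien_weight(np.clip(p, 0.0, 1.0))
    return out
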