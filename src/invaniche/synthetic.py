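"""Virtual-species landscapes and occurrence simulators.

This module manufactures the inputs the modeling chain expects from real
data — spatially autocorrelated, partially collinear climate layers; a
clustered host-plant raster; a habitat-class map; a DEM — plus occurrence
samples from a known generative niche.  Two sampling regimes are provided:

* *equilibrium* sampling, where occurrences are drawn across the whole
  landscape in proportion to true suitability (a native range in
  pseudo-equilibrium with climate), and
* *invasion-front* simulation, where yearly spread is limited to a
  dispersal radius around previously occupied cells, so the occupied
  climate envelope is a truncated subset of the full niche.

The generative parameters (:class:`VirtualSpeciesTruth`) are retained as
the oracle against which fitted models are checked.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree
from scipy.special import expit

from .raster import GridRaster, stack_geometry

__all__ = [
    "LandscapeBundle",
    "VirtualSpeciesTruth",
    "generate_climate",
    "generate_habitat",
    "make_landscape",
    "true_suitability",
    "sample_occurrences_equilibrium",
    "simulate_invasion",
]

OCC_COLUMNS = ["x", "y", "year", "severity", "source"]


@dataclass
class LandscapeBundle:
    """All spatial layers of one study region, on a shared grid.

    ``climate`` maps layer names to value rasters; ``host`` is a 0/1 raster
    of host-plant presence; ``habitat`` an integer class raster (1..C);
    ``dem`` elevation in metres; ``basal_area`` stand basal area (m²/ha).
    """

    climate: dict[str, GridRaster]
    host: GridRaster
    habitat: GridRaster
    dem: GridRaster
    basal_area: GridRaster | None = None
    forest_classes: tuple[int, ...] = (1, 2)

    def __post_init__(self) -> None:
        layers = dict(self.climate)
        layers["host"] = self.host
        layers["habitat"] = self.habitat
        layers["dem"] = self.dem
        if self.basal_area is not None:
            layers["basal_area"] = self.basal_area
        stack_geometry(layers)

    @property
    def cell_km(self) -> float:
        return self.host.cell_km

    @property
    def shape(self) -> tuple[int, int]:
        return self.host.shape

    def climate_table(self, rows, cols) -> pd.DataFrame:
        """Climate covariates at the given cells, one row per cell."""
        return pd.DataFrame(
            {name: r.values[rows, cols] for name, r in self.climate.items()}
        )


@dataclass
class VirtualSpeciesTruth:
    """Generative niche: logit-quadratic climate response, optional host
    dependence, a yearly dispersal ceiling, and ordinal severity cutpoints.

    Suitability is s(x) = expit(a0 + Σ_j a1_j z_j + a2_j z_j²) over
    standardized climate layers z_j; a2_j ≤ 0 keeps every marginal response
    unimodal, which the fitted model's linear+quadratic features can
    represent.  Severity (1–4) comes from three ordered cutpoints on s plus
    a small uniform jitter so the label is informative but not
    deterministic.
    """

    a0: float
    a1: dict[str, float]
    a2: dict[str, float]
    host_dependent: bool = True
    dispersal_radius_km: float = 10.0
    severity_cutpoints: tuple[float, float, float] = (0.3, 0.5, 0.7)
    severity_jitter: float = 0.05
    # exponent on a habitat-quality index (normalized stand basal area):
    # occupancy probability scales with quality^affinity, while impact
    # severity stays a function of climate suitability alone — presence is
    # partly habitat-driven, severe damage climate-driven
    habitat_affinity: float = 0.0
    # fixed standardization constants (mu, sd) per layer; None standardizes
    # over the supplied stack.  Fixed constants keep one niche definition
    # valid across regions whose climate envelopes differ.
    standardize: dict[str, tuple[float, float]] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if set(self.a1) != set(self.a2):
            raise ValueError("a1 and a2 must cover the same climate layers")
        for name, coef in self.a2.items():
            if coef > 0:
                raise ValueError(f"quadratic coefficient for '{name}' must be <= 0")
        cp = self.severity_cutpoints
        if not (0 < cp[0] < cp[1] < cp[2] < 1):
            raise ValueError("severity cutpoints must be strictly increasing in (0,1)")

    def to_dict(self) -> dict:
        return asdict(self)


def generate_climate(
    n_rows: int,
    n_cols: int,
    cell_km: float,
    n_vars: int,
    target_correlation: np.ndarray | None = None,
    autocorr_range_km: float = 5.0,
    seed: int = 0,
    names: list[str] | None = None,
) -> dict[str, GridRaster]:
    """Spatially autocorrelated climate layers with prescribed collinearity.

    Each layer starts as white noise convolved with a Gaussian kernel of
    scale ``autocorr_range_km``.  The smoothed fields are then empirically
    whitened and mixed through a symmetric square root of the target
    correlation matrix, so the realized pairwise Pearson correlations over
    cells equal the target (up to the rank of the target matrix).  Layers
    are standardized to mean 0, sd 1 over cells.
    """
    if target_correlation is None:
        target_correlation = np.eye(n_vars)
    target_correlation = np.asarray(target_correlation, dtype=float)
    if target_correlation.shape != (n_vars, n_vars):
        raise ValueError("target correlation matrix has wrong dimension")
    if not np.allclose(target_correlation, target_correlation.T):
        raise ValueError("target correlation matrix must be symmetric")
    eigval, eigvec = np.linalg.eigh(target_correlation)
    if eigval.min() < -1e-10:
        raise ValueError(
            "target correlation matrix is not positive semi-definite "
            f"(min eigenvalue {eigval.min():.3g})"
        )
    eigval = np.clip(eigval, 0.0, None)
    mixing = eigvec @ np.diag(np.sqrt(eigval)) @ eigvec.T

    rng = np.random.default_rng(seed)
    sigma_cells = max(autocorr_range_km / cell_km, 0.0)
    fields = np.empty((n_rows * n_cols, n_vars))
    for j in range(n_vars):
        white = rng.standard_normal((n_rows, n_cols))
        smooth = ndimage.gaussian_filter(white, sigma=sigma_cells, mode="reflect")
        fields[:, j] = smooth.ravel()
    fields -= fields.mean(axis=0)
    # Empirical whitening: removes incidental correlation between the
    # independent smooth fields before the target structure is imposed.
    cov = fields.T @ fields / fields.shape[0]
    w_val, w_vec = np.linalg.eigh(cov)
    whiten = w_vec @ np.diag(1.0 / np.sqrt(np.maximum(w_val, 1e-300))) @ w_vec.T
    mixed = fields @ whiten @ mixing
    sd = mixed.std(axis=0)
    sd[sd == 0] = 1.0
    mixed = mixed / sd

    if names is None:
        names = [f"clim{j + 1}" for j in range(n_vars)]
    return {
        names[j]: GridRaster(mixed[:, j].reshape(n_rows, n_cols), cell_km=cell_km)
        for j in range(n_vars)
    }


def generate_habitat(
    grid_shape: tuple[int, int],
    n_classes: int,
    host_prevalence: float,
    clustering_range_km: float = 5.0,
    cell_km: float = 1.0,
    seed: int = 0,
) -> tuple[GridRaster, GridRaster, GridRaster, GridRaster]:
    """Clustered habitat classes, host raster, DEM and basal area.

    Classes are quantile slices of a smoothed Gaussian field, so mean patch
    size grows with ``clustering_range_km``; a vanishing range degenerates
    to i.i.d. per-cell classes.  The host raster thresholds a second smooth
    field at the (1 − prevalence) quantile, giving a clustered host map
    whose cell fraction matches the requested prevalence.  DEM is a smooth
    non-negative field (metres); basal area a smooth field in a forestry
    range (m²/ha).

    Returns (habitat, host, dem, basal_area).
    """
    if n_classes < 1:
        raise ValueError("n_classes must be >= 1")
    if not 0 < host_prevalence <= 1:
        raise ValueError("host_prevalence must be in (0, 1]")
    n_rows, n_cols = grid_shape
    rng = np.random.default_rng(seed)
    sigma = clustering_range_km / cell_km

    def smooth_field() -> np.ndarray:
        white = rng.standard_normal((n_rows, n_cols))
        if sigma > 0:
            f = ndimage.gaussian_filter(white, sigma=sigma, mode="reflect")
        else:
            f = white
        # rank-uniformize so quantile thresholds cut exact fractions
        order = np.argsort(f, axis=None, kind="stable")
        u = np.empty(f.size)
        u[order] = (np.arange(f.size) + 0.5) / f.size
        return u.reshape(f.shape)

    habitat_u = smooth_field()
    habitat = np.ceil(habitat_u * n_classes).astype(float)
    habitat = np.clip(habitat, 1, n_classes)

    if host_prevalence >= 1.0:
        host = np.ones(grid_shape)
    else:
        host_u = smooth_field()
        host = (host_u >= 1.0 - host_prevalence).astype(float)

    dem_white = rng.standard_normal((n_rows, n_cols))
    dem_sigma = max(sigma, 3.0)
    dem = ndimage.gaussian_filter(dem_white, sigma=dem_sigma, mode="reflect")
    dem = (dem - dem.min()) / max(np.ptp(dem), 1e-12) * 1500.0  # 0..1500 m

    ba_white = rng.standard_normal((n_rows, n_cols))
    ba = ndimage.gaussian_filter(ba_white, sigma=max(sigma, 2.0), mode="reflect")
    ba = (ba - ba.min()) / max(np.ptp(ba), 1e-12) * 35.0 + 5.0  # 5..40 m²/ha

    mk = lambda v: GridRaster(v, cell_km=cell_km)
    return mk(habitat), mk(host), mk(dem), mk(ba)


def make_landscape(
    n_rows: int = 150,
    n_cols: int = 150,
    cell_km: float = 1.0,
    n_climate: int = 4,
    target_correlation: np.ndarray | None = None,
    autocorr_range_km: float = 5.0,
    n_classes: int = 5,
    host_prevalence: float = 0.25,
    habitat_range_km: float | None = None,
    seed: int = 0,
    climate_names: list[str] | None = None,
    climate_shift: dict[str, float] | None = None,
    climate_scale: dict[str, float] | None = None,
) -> LandscapeBundle:
    """Convenience constructor assembling a full :class:`LandscapeBundle`.

    ``climate_shift`` adds a constant to named climate layers after
    generation and ``climate_scale`` multiplies them — the handles used to
    build regions whose climate envelopes differ: a broad native range
    (large scale) versus an invaded range offset from the niche optimum
    (shift), covering only part of the species' niche.
    """
    climate = generate_climate(
        n_rows,
        n_cols,
        cell_km,
        n_climate,
        target_correlation,
        autocorr_range_km,
        seed=seed,
        names=climate_names,
    )
    if climate_scale:
        for name, factor in climate_scale.items():
            if name not in climate:
                raise KeyError(f"unknown climate layer '{name}'")
            climate[name] = climate[name].like(climate[name].values * factor)
    if climate_shift:
        for name, delta in climate_shift.items():
            if name not in climate:
                raise KeyError(f"unknown climate layer '{name}'")
            climate[name] = climate[name].like(climate[name].values + delta)
    habitat, host, dem, ba = generate_habitat(
        (n_rows, n_cols),
        n_classes,
        host_prevalence,
        # habitat structure is typically finer-grained than climate
        clustering_range_km=(
            habitat_range_km if habitat_range_km is not None else autocorr_range_km
        ),
        cell_km=cell_km,
        seed=seed + 1,
    )
    return LandscapeBundle(climate=climate, host=host, habitat=habitat, dem=dem, basal_area=ba)


def true_suitability(truth: VirtualSpeciesTruth, climate: dict[str, GridRaster]) -> GridRaster:
    """True occurrence suitability s(x) in (0,1) on the landscape grid.

    s(x) = expit(a0 + Σ_j a1_j z_j(x) + a2_j z_j(x)²) with z_j the
    standardized climate layers (standardization over unmasked cells of the
    given stack; generated layers are already standard normal).
    """
    missing = [name for name in truth.a1 if name not in climate]
    if missing:
        raise KeyError(f"climate stack missing layers required by truth: {missing}")
    template = stack_geometry(dict(climate))
    eta = np.full(template.shape, truth.a0, dtype=float)
    for name in truth.a1:
        vals = climate[name].values
        if truth.standardize is not None and name in truth.standardize:
            mu, sd = truth.standardize[name]
        else:
            mu, sd = np.nanmean(vals), np.nanstd(vals)
        z = (vals - mu) / (sd if sd > 0 else 1.0)
        eta = eta + truth.a1[name] * z + truth.a2[name] * z**2
    return template.like(expit(eta))


def _severity_from_suitability(
    s: np.ndarray, truth: VirtualSpeciesTruth, rng: np.random.Generator
) -> np.ndarray:
    jitter = rng.uniform(-truth.severity_jitter, truth.severity_jitter, size=s.shape)
    noisy = np.clip(s + jitter, 0.0, 1.0)
    return 1 + np.searchsorted(np.asarray(truth.severity_cutpoints), noisy).astype(int)


def _sampling_weights(
    truth: VirtualSpeciesTruth, landscape: LandscapeBundle
) -> tuple[np.ndarray, GridRaster]:
    suit = true_suitability(truth, landscape.climate)
    weight = np.where(np.isfinite(suit.values), suit.values, 0.0)
    if truth.host_dependent:
        weight = weight * np.nan_to_num(landscape.host.values)
    if truth.habitat_affinity and landscape.basal_area is not None:
        ba = np.nan_to_num(landscape.basal_area.values)
        quality = ba / max(ba.max(), 1e-12)
        weight = weight * quality**truth.habitat_affinity
    return weight, suit


def sample_occurrences_equilibrium(
    truth: VirtualSpeciesTruth,
    landscape: LandscapeBundle,
    n: int,
    seed: int = 0,
    year: int = 0,
) -> pd.DataFrame:
    """Equilibrium occurrence sample: cells drawn ∝ s(x) (× host presence).

    At most one occurrence per cell (cells are drawn without replacement),
    mirroring the de-clustering applied to real records.  Severity follows
    the truth's cutpoints on s with jitter.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    weight, suit = _sampling_weights(truth, landscape)
    flat = weight.ravel()
    positive = np.count_nonzero(flat > 0)
    if positive == 0:
        raise ValueError("no cell has positive sampling weight")
    n_draw = min(n, positive)
    rng = np.random.default_rng(seed)
    idx = rng.choice(flat.size, size=n_draw, replace=False, p=flat / flat.sum())
    rows, cols = np.unravel_index(idx, landscape.shape)
    x, y = landscape.host.xy_of(rows, cols)
    sev = _severity_from_suitability(suit.values[rows, cols], truth, rng)
    return pd.DataFrame(
        {"x": x, "y": y, "year": year, "severity": sev, "source": "simulated"}
    )


def simulate_invasion(
    truth: VirtualSpeciesTruth,
    landscape: LandscapeBundle,
    intro_points: list[tuple[float, float]],
    n_years: int,
    per_year_intensity: int = 50,
    seed: int = 0,
    start_year: int = 1,
) -> pd.DataFrame:
    """Dispersal-limited yearly spread from introduction points.

    Year 1 occupies the introduction cells.  Each later year, candidate
    cells lie within ``truth.dispersal_radius_km`` of any previously
    occupied cell; up to ``per_year_intensity`` new cells are occupied,
    drawn without replacement with probability ∝ s(x) × host(x).  The
    occupied set never shrinks; each newly occupied cell yields one record
    in its colonization year.
    """
    if n_years < 1:
        raise ValueError("n_years must be >= 1")
    if not intro_points:
        raise ValueError("at least one introduction point required")
    weight, suit = _sampling_weights(truth, landscape)
    rng = np.random.default_rng(seed)
    n_rows, n_cols = landscape.shape
    template = landscape.host

    occupied = np.zeros((n_rows, n_cols), dtype=bool)
    records: list[tuple[float, float, int, int]] = []
    for (px, py) in intro_points:
        r, c = template.cell_of(px, py)
        r, c = int(r), int(c)
        if not occupied[r, c]:
            occupied[r, c] = True
            x, y = template.xy_of(r, c)
            sev = _severity_from_suitability(
                np.array([suit.values[r, c]]), truth, rng
            )[0]
            records.append((float(x), float(y), start_year, int(sev)))

    radius = truth.dispersal_radius_km
    for t in range(1, n_years):
        year = start_year + t
        occ_rows, occ_cols = np.nonzero(occupied)
        if radius > 0:
            ox, oy = template.xy_of(occ_rows, occ_cols)
            tree = cKDTree(np.column_stack([np.atleast_1d(ox), np.atleast_1d(oy)]))
            cx, cy = template.cell_centers()
            dist, _ = tree.query(np.column_stack([cx.ravel(), cy.ravel()]))
            reachable = (dist.reshape(n_rows, n_cols) <= radius + 1e-9)
        else:
            reachable = occupied.copy()
        cand = reachable & ~occupied & (weight > 0)
        flat_idx = np.flatnonzero(cand.ravel())
        if flat_idx.size == 0:
            continue
        w = weight.ravel()[flat_idx]
        k = min(per_year_intensity, flat_idx.size)
        chosen = rng.choice(flat_idx, size=k, replace=False, p=w / w.sum())
        rows, cols = np.unravel_index(chosen, (n_rows, n_cols))
        occupied[rows, cols] = True
        xs, ys = template.xy_of(rows, cols)
        sevs = _severity_from_suitability(suit.values[rows, cols], truth, rng)
        for x, y, sev in zip(np.atleast_1d(xs), np.atleast_1d(ys), sevs):
            records.append((float(x), float(y), year, int(sev)))

    df = pd.DataFrame(records, columns=["x", "y", "year", "severity"])
    df["source"] = "simulated"
    return df
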