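"""Orchestration of the model chain.

The study design this package reproduces compares, for a non-equilibrium
invader:

1. three *climate* models — calibrated in the native range, in the invaded
   range, and in the invaded range with the background down-weighted by
   the native model's projection — each projected reciprocally onto the
   other region;
2. a pair of *regional* models at 1 km resolution — occurrence
   distribution and severe-impact — driven by the weighted climate
   model's suitability surface plus topographic, habitat-composition and
   dispersal-distance covariates, together with "Reduced" variants whose
   background is restricted to a 10 km buffer around presences and masked
   to the host distribution (removing the dominant distance and
   host-cover signals);
3. area summaries above a suitability threshold and a next-year
   projection with frozen coefficients and updated distance layers.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from . import background as bg
from . import evaluation as ev
from . import geo_features as gf
from . import maxent
from .raster import GridRaster, stack_geometry
from .synthetic import LandscapeBundle

__all__ = [
    "StudyConfig",
    "CovariateStack",
    "ModelSuite",
    "extract_covariates",
    "predict_raster",
    "run_climate_models",
    "build_regional_covariates",
    "run_regional_models",
    "area_summary",
    "project_next_year",
]

ASPECT_LEVELS = [1.0, 2.0, 3.0, 4.0]  # N, E, S, W; flat (0) is the reference


@dataclass
class StudyConfig:
    """All knobs of a study run, with the defaults used throughout.

    Background size defaults to 10,000 points per model extent; MaxEnt uses
    β-multiplier 3 with linear+quadratic features, 10 replicate fits on
    independent 70/30 presence splits; severity levels 3–4 count as "high";
    the Reduced models use a 10 km presence buffer; areas are summarized
    above 0.5 on the cloglog suitability scale.
    """

    r_threshold: float = 0.7
    vif_threshold: float = 10.0
    beta: float = 3.0
    n_replicates: int = 10
    train_fraction: float = 0.7
    n_background: int = 10000
    severity_threshold: int = 3
    buffer_km: float = 10.0
    area_threshold: float = 0.5
    cbi_windows: int = 101
    cbi_width: float = 0.02
    seed: int = 0

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class CovariateStack:
    """Named covariate rasters on one grid, with categorical flags."""

    rasters: dict[str, GridRaster]
    categorical: dict[str, list] = field(default_factory=dict)

    def __post_init__(self) -> None:
        stack_geometry(self.rasters)

    @property
    def template(self) -> GridRaster:
        return next(iter(self.rasters.values()))

    @property
    def names(self) -> list[str]:
        return list(self.rasters)

    def table_at_points(self, points: pd.DataFrame) -> pd.DataFrame:
        """Covariate rows at the cells containing the given (x, y) points."""
        row, col = self.template.cell_of(points["x"].to_numpy(), points["y"].to_numpy())
        return pd.DataFrame({n: r.values[row, col] for n, r in self.rasters.items()})

    def full_table(self) -> tuple[pd.DataFrame, np.ndarray]:
        """Covariates of every jointly valid cell + the validity mask."""
        valid = np.ones(self.template.shape, dtype=bool)
        for r in self.rasters.values():
            valid &= r.mask
        data = {n: r.values[valid] for n, r in self.rasters.items()}
        return pd.DataFrame(data), valid

    def drop(self, names: list[str]) -> "CovariateStack":
        return CovariateStack(
            rasters={n: r for n, r in self.rasters.items() if n not in names},
            categorical={n: l for n, l in self.categorical.items() if n not in names},
        )


@dataclass
class ModelSuite:
    """Fitted models plus their evaluations, contributions and curves."""

    models: dict = field(default_factory=dict)
    reports: dict = field(default_factory=dict)
    contributions: dict = field(default_factory=dict)
    response_curves: dict = field(default_factory=dict)
    predictions: dict = field(default_factory=dict)
    config: StudyConfig | None = None

    def to_dict(self) -> dict:
        return {
            "reports": {k: (v.to_dict() if hasattr(v, "to_dict") else v)
                        for k, v in self.reports.items()},
            "contributions": {k: dict(v) for k, v in self.contributions.items()},
            "models": {
                k: [m.to_dict() for m in getattr(v, "models", [v])]
                for k, v in self.models.items()
            },
            "config": self.config.to_dict() if self.config else None,
        }


def extract_covariates(points: pd.DataFrame, stack: dict[str, GridRaster]) -> pd.DataFrame:
    """Raster values at the cells containing each point, one column per layer."""
    template = stack_geometry(stack)
    row, col = template.cell_of(points["x"].to_numpy(), points["y"].to_numpy())
    return pd.DataFrame({n: r.values[row, col] for n, r in stack.items()})


def predict_raster(model, stack: CovariateStack | dict, output=None) -> GridRaster:
    """Model prediction over every valid cell of a covariate stack."""
    if isinstance(stack, dict):
        stack = CovariateStack(rasters=stack)
    table, valid = stack.full_table()
    preds = model.predict(table, output=output)
    out = np.full(stack.template.shape, np.nan)
    out[valid] = preds
    return stack.template.like(out)


def run_climate_models(
    native_occ: pd.DataFrame,
    invaded_occ: pd.DataFrame,
    native_climate: dict[str, GridRaster],
    invaded_climate: dict[str, GridRaster],
    config: StudyConfig | None = None,
) -> ModelSuite:
    """Fit the three climate models and their reciprocal transfer reports.

    ``clim_native`` uses a uniform background in the native region,
    ``clim_invaded`` a uniform background in the invaded region, and
    ``clim_weighted`` the invaded data with each background point
    down-weighted by the native model's projection at that point.  Each
    model is evaluated on its calibration region (replicate held-out
    splits) and transferred onto the opposite region's presences and
    background.
    """
    config = config or StudyConfig()
    if len(native_occ) == 0 or len(invaded_occ) == 0:
        raise ValueError("both occurrence sets must be non-empty")
    nat_template = stack_geometry(native_climate)
    inv_template = stack_geometry(invaded_climate)
    rng = np.random.default_rng(config.seed)
    seeds = rng.integers(0, 2**31 - 1, size=6)

    nat_bg_pts = bg.sample_background(nat_template, config.n_background, seed=int(seeds[0]))
    inv_bg_pts = bg.sample_background(inv_template, config.n_background, seed=int(seeds[1]))
    nat_bg = extract_covariates(nat_bg_pts, native_climate)
    inv_bg = extract_covariates(inv_bg_pts, invaded_climate)
    nat_pres = extract_covariates(native_occ, native_climate)
    inv_pres = extract_covariates(invaded_occ, invaded_climate)

    suite = ModelSuite(config=config)

    ens_nat, reps_nat = maxent.replicate_fit(
        nat_pres, nat_bg, n_replicates=config.n_replicates,
        train_fraction=config.train_fraction, beta=config.beta, seed=int(seeds[2]),
    )
    ens_inv, reps_inv = maxent.replicate_fit(
        inv_pres, inv_bg, n_replicates=config.n_replicates,
        train_fraction=config.train_fraction, beta=config.beta, seed=int(seeds[3]),
    )
    weighted = bg.weight_background(inv_bg, ens_nat)
    if not np.any(weighted["weight"].to_numpy() > 0):
        raise ValueError(
            "all background weights are zero: native model saturates the invaded region"
        )
    ens_wgt, reps_wgt = maxent.replicate_fit(
        inv_pres, inv_bg, weights=weighted["weight"].to_numpy(),
        n_replicates=config.n_replicates, train_fraction=config.train_fraction,
        beta=config.beta, seed=int(seeds[4]),
    )

    suite.models = {
        "clim_native": ens_nat, "clim_invaded": ens_inv, "clim_weighted": ens_wgt,
    }
    for name, reps in [("clim_native", reps_nat), ("clim_invaded", reps_inv),
                       ("clim_weighted", reps_wgt)]:
        if reps:
            suite.reports[f"{name}_calibration"] = ev.average_reports(reps)
    # full-data calibration reports (resubstitution) for completeness
    suite.reports["clim_native_self"] = ev.evaluate_model(ens_nat, nat_pres, nat_bg).to_dict()
    suite.reports["clim_invaded_self"] = ev.evaluate_model(ens_inv, inv_pres, inv_bg).to_dict()
    suite.reports["clim_weighted_self"] = ev.evaluate_model(ens_wgt, inv_pres, inv_bg).to_dict()
    # reciprocal transfers
    suite.reports["clim_native_transfer"] = ev.transfer_report(ens_nat, inv_pres, inv_bg).to_dict()
    suite.reports["clim_invaded_transfer"] = ev.transfer_report(ens_inv, nat_pres, nat_bg).to_dict()
    suite.reports["clim_weighted_transfer"] = ev.transfer_report(ens_wgt, nat_pres, nat_bg).to_dict()

    for name, ens in suite.models.items():
        suite.contributions[name] = maxent.variable_contribution(
            ens, inv_pres if name != "clim_native" else nat_pres,
            inv_bg if name != "clim_native" else nat_bg, seed=int(seeds[5]),
        )
    return suite


def build_regional_covariates(
    landscape: LandscapeBundle,
    climate_suitability: GridRaster,
    occ_prev_year: pd.DataFrame,
    severity_threshold: int = 3,
    variant: str = "distribution",
) -> CovariateStack:
    """Assemble the regional covariate stack at the landscape resolution.

    Layers: climate suitability rescaled to percent, elevation, aspect
    categories, forest cover and mean basal area in a 1 km radius,
    fragmentation and heterogeneity per km² block, host cover in a 10 km
    radius, and the minimum distance (m) to the previous year's
    observations — all records for the ``distribution`` variant, only
    records at or above ``severity_threshold`` for the ``severity``
    variant (erroring when none exist).
    """
    if len(occ_prev_year) == 0:
        raise ValueError("previous-year occurrence set is empty")
    if variant not in ("distribution", "severity"):
        raise ValueError("variant must be 'distribution' or 'severity'")
    forest = landscape.habitat.like(
        np.isin(landscape.habitat.values, landscape.forest_classes).astype(float)
    )
    frag, het = gf.patch_metrics(landscape.habitat, block_km=1.0)
    if variant == "severity":
        high = occ_prev_year[occ_prev_year["severity"] >= severity_threshold]
        if len(high) == 0:
            raise ValueError(
                f"no previous-year records with severity >= {severity_threshold}"
            )
        dist = gf.min_distance_map(high, landscape.host, units="m")
    else:
        dist = gf.min_distance_map(occ_prev_year, landscape.host, units="m")
    basal = landscape.basal_area
    if basal is None:
        basal = landscape.host.like(np.zeros(landscape.shape))
    rasters = {
        "climate_suitability": climate_suitability.like(
            climate_suitability.values * 100.0
        ),
        "elevation": landscape.dem,
        "aspect": gf.aspect_category(landscape.dem),
        "forest_cover_1km": gf.focal_percentage(forest, 1.0),
        "basal_area_1km": gf.focal_mean(basal, 1.0),
        "fragmentation": frag,
        "heterogeneity": het,
        "host_cover_10km": gf.focal_percentage(landscape.host, 10.0),
        "min_distance": dist,
    }
    return CovariateStack(rasters=rasters, categorical={"aspect": ASPECT_LEVELS})


REDUCED_EXCLUDES = ["min_distance", "host_cover_10km"]


def run_regional_models(
    occ_current: pd.DataFrame,
    covariates_dist: CovariateStack,
    covariates_sever: CovariateStack,
    host_mask: np.ndarray,
    config: StudyConfig | None = None,
) -> ModelSuite:
    """Fit the distribution/severity models and their Reduced variants.

    ``dist`` and ``sever`` use a uniform background over the region;
    ``dist_reduced`` and ``sever_reduced`` use a 10 km presence-buffered,
    host-masked background and omit the distance and host-cover layers.
    The severity models take only high-severity records as presences.
    """
    config = config or StudyConfig()
    if len(occ_current) < 20:
        raise ValueError("need at least 20 current-year occurrences")
    high = occ_current[occ_current["severity"] >= config.severity_threshold]
    template = covariates_dist.template
    rng = np.random.default_rng(config.seed)
    seeds = rng.integers(0, 2**31 - 1, size=8)

    suite = ModelSuite(config=config)

    def fit_one(name, presences_pts, stack, buffered):
        if buffered:
            pts = bg.buffered_background(
                presences_pts, template, buffer_km=config.buffer_km,
                n=config.n_background, seed=int(seeds[len(suite.models)]),
                host_mask=host_mask,
            )
            stack = stack.drop(REDUCED_EXCLUDES)
        else:
            pts = bg.sample_background(
                template, config.n_background, seed=int(seeds[len(suite.models)])
            )
        pres_cov = stack.table_at_points(presences_pts)
        bg_cov = stack.table_at_points(pts)
        ens, reps = maxent.replicate_fit(
            pres_cov, bg_cov, n_replicates=config.n_replicates,
            train_fraction=config.train_fraction, beta=config.beta,
            categoricals=stack.categorical, seed=int(seeds[4 + len(suite.models) % 4]),
        )
        suite.models[name] = ens
        if reps:
            suite.reports[f"{name}_calibration"] = ev.average_reports(reps)
        suite.reports[f"{name}_self"] = ev.evaluate_model(ens, pres_cov, bg_cov).to_dict()
        suite.contributions[name] = maxent.variable_contribution(
            ens, pres_cov, bg_cov, seed=int(seeds[7])
        )
        for v in ens.variables:
            suite.response_curves[(name, v)] = maxent.response_curve(ens, v)
        suite.predictions[name] = predict_raster(ens, stack)

    fit_one("dist", occ_current, covariates_dist, buffered=False)
    fit_one("dist_reduced", occ_current, covariates_dist, buffered=True)
    if len(high) >= 20:
        fit_one("sever", high, covariates_sever, buffered=False)
        fit_one("sever_reduced", high, covariates_sever, buffered=True)
    else:
        raise ValueError(
            f"need at least 20 high-severity occurrences, got {len(high)}"
        )
    return suite


def area_summary(prediction: GridRaster, threshold: float, cell_km: float | None = None) -> float:
    """Hectares of unmasked cells predicted at or above the threshold."""
    if not 0 < threshold < 1:
        raise ValueError("threshold must lie in (0, 1)")
    cell_km = cell_km if cell_km is not None else prediction.cell_km
    n = int(np.nansum(prediction.values >= threshold))
    return n * cell_km**2 * 100.0  # 1 km² = 100 ha


def project_next_year(
    suite: ModelSuite,
    occ_current: pd.DataFrame,
    landscape: LandscapeBundle,
    climate_suitability: GridRaster,
    config: StudyConfig | None = None,
) -> dict:
    """Next-year projection: frozen coefficients, updated distance layers.

    Rebuilds the distribution and severity covariate stacks with the
    minimum-distance layers recomputed from the *current* year's records,
    re-predicts with the already-fitted models, masks the maps by the host
    distribution, and summarizes suitable areas.
    """
    config = config or StudyConfig()
    host = np.nan_to_num(landscape.host.values) > 0
    out = {"predictions": {}, "areas_ha": {}}
    for name, variant in [("dist", "distribution"), ("sever", "severity")]:
        if name not in suite.models:
            continue
        stack = build_regional_covariates(
            landscape, climate_suitability, occ_current,
            severity_threshold=config.severity_threshold, variant=variant,
        )
        pred = predict_raster(suite.models[name], stack)
        masked = pred.like(np.where(host, pred.values, np.nan))
        out["predictions"][name] = masked
        out["areas_ha"][name] = area_summary(masked, config.area_threshold)
    return out
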