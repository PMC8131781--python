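"""Occurrence tables, configuration, and run manifests.

Occurrence CSVs carry columns ``x, y, year, severity[, source]`` with
coordinates in km on the study grid.  Reading applies the same hygiene the
analysis expects of field data: rows with missing coordinates or year are
dropped (and counted), exact duplicate (x, y, year) rows collapse to one,
and optional grid-cell thinning keeps at most one record per cell per year
(the stand-in for removing spatially clustered records; the clustering
rule in field datasets is rarely stated, so one-per-cell is the default).
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .raster import GridRaster, read_ascii_grid, write_ascii_grid

logger = logging.getLogger(__name__)

__all__ = [
    "read_occurrences",
    "write_occurrences",
    "read_raster",
    "write_raster",
    "load_config",
    "RunManifest",
    "run_from_config",
]

OCC_REQUIRED = ["x", "y", "year", "severity"]


def read_occurrences(
    path,
    dedupe: bool = True,
    thin_cell_km: float | None = None,
) -> pd.DataFrame:
    """Read and clean an occurrence CSV.

    ``thin_cell_km`` enables one-record-per-grid-cell-per-year thinning at
    the given cell size (the first record in file order wins).  Raises if
    nothing survives filtering.
    """
    df = pd.read_csv(path)
    missing_cols = [c for c in OCC_REQUIRED if c not in df.columns]
    if missing_cols:
        raise ValueError(f"occurrence file missing columns: {missing_cols}")
    if "source" not in df.columns:
        df["source"] = "observed"
    n0 = len(df)
    df = df.dropna(subset=["x", "y", "year"])
    n_dropped = n0 - len(df)
    if n_dropped:
        logger.info("dropped %d rows with missing coordinates/year", n_dropped)
    if dedupe:
        df = df.drop_duplicates(subset=["x", "y", "year"], keep="first")
    if thin_cell_km:
        cell = (
            np.floor(df["x"] / thin_cell_km).astype(int).astype(str)
            + "_"
            + np.floor(df["y"] / thin_cell_km).astype(int).astype(str)
            + "_"
            + df["year"].astype(int).astype(str)
        )
        df = df.loc[~cell.duplicated(keep="first")]
    if len(df) == 0:
        raise ValueError("no occurrence records remain after filtering")
    df = df.reset_index(drop=True)
    df["year"] = df["year"].astype(int)
    df["severity"] = df["severity"].astype(int)
    return df


def write_occurrences(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def read_raster(path) -> GridRaster:
    """Read a single-band raster (ESRI ASCII grid)."""
    return read_ascii_grid(path)


def write_raster(raster: GridRaster, path) -> None:
    write_ascii_grid(raster, path)


def load_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def _digest(path: Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


class RunManifest:
    """Provenance record of one run: config, seeds, outputs, digests."""

    def __init__(self, config: dict, seed: int):
        self.data = {
            "config": config,
            "seed": seed,
            "stages": [],
            "outputs": {},
        }
        self._t0 = time.time()

    def add_stage(self, name: str) -> None:
        self.data["stages"].append({"name": name, "elapsed_s": round(time.time() - self._t0, 3)})

    def add_output(self, path) -> None:
        path = Path(path)
        self.data["outputs"][str(path)] = _digest(path)

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.data, fh, indent=1, sort_keys=True)

    def to_dict(self) -> dict:
        return self.data


def run_from_config(config_path, out_dir, seed: int | None = None) -> RunManifest:
    """Execute the stages named in a YAML config in dependency order.

    Supported stages: ``simulate`` (landscape + occurrences from a virtual
    species) and ``pipeline`` (the regional model chain on the simulated
    data).  Every random stream derives from the root seed.  Outputs and
    their digests are inventoried in ``manifest.json``.
    """
    from . import experiments
    from .synthetic import (
        VirtualSpeciesTruth, make_landscape, sample_occurrences_equilibrium,
    )

    cfg = load_config(config_path)
    stages = cfg.get("stages", ["simulate"])
    known = {"simulate", "pipeline"}
    unknown = set(stages) - known
    if unknown:
        raise ValueError(f"unknown stage(s): {sorted(unknown)}")
    if "pipeline" in stages and "simulate" not in stages:
        raise ValueError("pipeline stage requires the simulate stage")
    seed = int(cfg.get("seed", 0) if seed is None else seed)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(cfg, seed)

    sim = cfg.get("simulate", {})
    grid = tuple(sim.get("grid", [120, 120]))
    if "simulate" in stages:
        land = make_landscape(
            grid[0], grid[1],
            cell_km=float(sim.get("cell_km", 1.0)),
            host_prevalence=float(sim.get("host_prevalence", 0.25)),
            seed=seed,
        )
        truth = VirtualSpeciesTruth(
            a0=float(sim.get("a0", 1.0)),
            a1={k: float(v) for k, v in sim.get("a1", {"clim1": 0.0}).items()},
            a2={k: float(v) for k, v in sim.get("a2", {"clim1": -2.0}).items()},
            host_dependent=bool(sim.get("host_dependent", True)),
            dispersal_radius_km=float(sim.get("dispersal_radius_km", 10.0)),
            seed=seed,
        )
        occ = sample_occurrences_equilibrium(
            truth, land, int(sim.get("n_occurrences", 300)), seed=seed + 1
        )
        occ_path = out / "occurrences.csv"
        write_occurrences(occ, occ_path)
        manifest.add_output(occ_path)
        truth_path = out / "truth.json"
        with open(truth_path, "w") as fh:
            json.dump(truth.to_dict(), fh, indent=1)
        manifest.add_output(truth_path)
        for name, r in land.climate.items():
            p = out / f"{name}.asc"
            write_raster(r, p)
            manifest.add_output(p)
        for name, r in [("host", land.host), ("habitat", land.habitat), ("dem", land.dem)]:
            p = out / f"{name}.asc"
            write_raster(r, p)
            manifest.add_output(p)
        manifest.add_stage("simulate")

    if "pipeline" in stages:
        result = experiments.regional_split(
            seed=seed,
            grid=grid,
            cell_km=float(sim.get("cell_km", 0.5)),
            n_background=int(cfg.get("pipeline", {}).get("n_background", 5000)),
        )
        report = {
            "contributions": {k: dict(v) for k, v in result["contributions"].items()},
            "reports": result["suite"].to_dict()["reports"],
        }
        report_path = out / "report.json"
        with open(report_path, "w") as fh:
            json.dump(report, fh, indent=1, sort_keys=True)
        manifest.add_output(report_path)
        manifest.add_stage("pipeline")

    manifest.save(out / "manifest.json")
    return manifest
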