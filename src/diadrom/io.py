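"""Loading and serialization shared by the CLI and scripts.

Tables are long/tidy CSV; species parameters and run settings are YAML with
strict key checking (unknown or missing species parameters are an error, no
silent defaults for a partially specified file).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import platform
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from .demography import SpeciesParameters, ThermalResponse
from .engine import SimulationConfig, SimulationResult
from .environment import BasinNetwork, ClimateSeries


def load_basins(path: str | Path, distances_path: str | Path | None = None) -> BasinNetwork:
    """Read a basin table CSV (id,lon,lat,surface_area_km2[,main_stem_km])
    and an optional id-labelled square distance matrix CSV."""
    frame = pd.read_csv(path)
    distances = None
    if distances_path is not None:
        dm = pd.read_csv(distances_path, index_col=0)
        order = [str(i) for i in frame["id"]]
        dm.index = dm.index.astype(str)
        dm.columns = dm.columns.astype(str)
        distances = dm.loc[order, order].to_numpy(dtype=float)
    return BasinNetwork.from_frame(frame, distances=distances)


def load_climate(path: str | Path) -> ClimateSeries:
    """Read a long-format climate CSV (basin_id,year,season,temperature_C[,medium])."""
    table = pd.read_csv(path)
    medium = "water"
    if "medium" in table.columns:
        media = set(table["medium"].unique())
        if len(media) != 1:
            raise ValueError("climate table mixes air and water temperatures")
        medium = media.pop()
        table = table.drop(columns=["medium"])
    return ClimateSeries(table, medium=medium)


def load_species_parameters(path: str | Path, require_complete: bool = True) -> SpeciesParameters:
    """Read a species parameter YAML, rejecting unknown keys.

    With ``require_complete`` (the default for files fed to the CLI) every
    life-history parameter must be present explicitly — a missing one is an
    error naming the parameter, never a silent default.
    """
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ValueError("species parameter file must be a mapping")
    if require_complete:
        known = {f.name for f in dataclasses.fields(SpeciesParameters)}
        missing = sorted(known - set(data))
        if missing:
            raise KeyError(f"species parameter file missing: {missing}")
    return SpeciesParameters.from_mapping(data)


def dump_species_parameters(p: SpeciesParameters, path: str | Path) -> None:
    data: dict[str, Any] = {}
    for f in dataclasses.fields(p):
        v = getattr(p, f.name)
        if isinstance(v, ThermalResponse):
            v = [v.t_min, v.t_opt, v.t_max]
        data[f.name] = v
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)


def load_simulation_config(path: str | Path) -> SimulationConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    known = {f.name for f in dataclasses.fields(SimulationConfig)}
    unknown = set(data) - known
    if unknown:
        raise KeyError(f"unknown simulation settings: {sorted(unknown)}")
    return SimulationConfig(**data)


def result_to_frame(result: SimulationResult) -> pd.DataFrame:
    """Tidy per-(basin, year) export of a simulation result."""
    rows = []
    for yi, year in enumerate(result.years):
        for bi, bid in enumerate(result.basin_ids):
            rows.append(
                {
                    "basin_id": bid,
                    "year": int(year),
                    "recruits": result.recruits[yi, bi],
                    "spawners": result.spawners[yi, bi],
                    "reproduced": bool(result.reproduced[yi, bi]),
                    "first_spawner_age": result.first_spawner_age[yi, bi],
                }
            )
    return pd.DataFrame(rows)


def result_to_json(result: SimulationResult, p_sust_window: int | None = None) -> dict:
    from .engine import persistence_probability

    out = {
        "basin_ids": result.basin_ids,
        "latitudes": result.latitudes.tolist(),
        "years": result.years.tolist(),
        "recruits": result.recruits.tolist(),
        "spawners": result.spawners.tolist(),
        "reproduced": result.reproduced.astype(int).tolist(),
        "first_spawner_age": np.where(
            np.isnan(result.first_spawner_age), None, result.first_spawner_age
        ).tolist(),
        "ticks": result.ticks,
        "seed": result.seed,
    }
    if p_sust_window is not None:
        out["p_sust"] = persistence_probability(result, p_sust_window).tolist()
        out["p_sust_window_years"] = p_sust_window
    return out


def run_manifest(seed: int, config: dict) -> dict:
    """Reproducibility manifest: config hash, seed and version stamps."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    import diadrom

    return {
        "seed": seed,
        "config_sha256": hashlib.sha256(blob).hexdigest(),
        "package_version": diadrom.__version__,
        "numpy_version": np.__version__,
        "python_version": platform.python_version(),
    }
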