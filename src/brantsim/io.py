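"""Delimited-text and YAML interfaces for the simulator and statistics."""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .engine import SimulationResult
from .environment import EelgrassParams, TideSeries
from .foragers import EnergeticsParams

PATCH_COLUMNS = ["id", "subsite", "elevation_m", "area_m2",
                 "jan_biomass_g_m2", "jan_shoot_m"]
SCENARIO_COLUMNS = ["year", "jan_biomass_g_m2", "jan_shoot_m",
                    "winter_population", "sea_level_m"]


def read_patch_map(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(PATCH_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"patch map missing columns: {sorted(missing)}")
    return df[PATCH_COLUMNS]


def write_patch_map(bay: pd.DataFrame, path) -> None:
    bay[PATCH_COLUMNS].to_csv(path, index=False)


def read_tide(path) -> TideSeries:
    df = pd.read_csv(path)
    if not {"datetime", "height_m"} <= set(df.columns):
        raise ValueError("tide file needs columns datetime, height_m")
    return TideSeries(heights=df["height_m"].to_numpy(dtype=float))


def write_tide(tide: TideSeries, path, start: str = "2000-08-01") -> None:
    idx = pd.date_range(start, periods=len(tide.heights), freq="h")
    pd.DataFrame({"datetime": idx, "height_m": tide.adjusted}).to_csv(
        path, index=False)


def read_scenarios(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(SCENARIO_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"scenario table missing columns: {sorted(missing)}")
    return df


def write_scenarios(df: pd.DataFrame, path) -> None:
    df[SCENARIO_COLUMNS].to_csv(path, index=False)


def load_params(path) -> tuple[EnergeticsParams, EelgrassParams, dict]:
    """Read a YAML config with sections brant, eelgrass, tide, light.

    Unknown keys are rejected; omitted keys keep their documented defaults.
    Returns (energetics, eelgrass, extra) where ``extra`` holds the tide and
    light sections verbatim.
    """
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}

    def build(cls, section):
        data = cfg.get(section, {}) or {}
        names = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - names
        if unknown:
            raise ValueError(f"unknown keys in [{section}]: {sorted(unknown)}")
        # YAML maps with tuple-like values come back as lists
        data = {k: tuple(v) if isinstance(v, list) else v
                for k, v in data.items()}
        return cls(**data)

    energetics = build(EnergeticsParams, "brant")
    eelgrass = build(EelgrassParams, "eelgrass")
    extra = {k: cfg.get(k, {}) for k in ("tide", "light")}
    return energetics, eelgrass, extra


def save_params(energetics: EnergeticsParams, eelgrass: EelgrassParams,
                path, extra: dict | None = None) -> None:
    def scrub(v):
        if isinstance(v, tuple):
            return [scrub(x) for x in v]
        if isinstance(v, dict):
            return {("|".join(k) if isinstance(k, tuple) else k): scrub(x)
                    for k, x in v.items()}
        return v

    def plain(obj):
        return {k: scrub(v) for k, v in dataclasses.asdict(obj).items()}

    cfg = {"brant": plain(energetics), "eelgrass": plain(eelgrass)}
    cfg.update(extra or {})
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)


def write_result(result: SimulationResult, outdir, label: str = "run") -> None:
    """Write one run's outputs: summary, per-flock table, daily patch biomass,
    and a log with the seed."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    pd.Series(result.summary, name="value").rename_axis("metric").to_csv(
        outdir / f"{label}_summary.csv")
    result.flocks.to_csv(outdir / f"{label}_flocks.csv", index=False)
    result.patch_biomass.to_csv(outdir / f"{label}_patch_biomass.csv")
    log = {"seed": int(result.seed),
           "n_flocks": int(len(result.flocks)),
           "n_patches": int(result.patch_biomass.shape[1])}
    (outdir / f"{label}_log.json").write_text(json.dumps(log, indent=2))
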