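"""Configuration loading, validation and the run manifest.

The config is a YAML mapping with a fixed schema; unknown keys anywhere are
rejected, defaults are filled in, and the fully resolved configuration is
hashed so every output can name the exact inputs that produced it.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Any

import numpy as np
import yaml

from . import __version__
from .builder import BrushRecipe
from .protocol import CompressionSchedule
from .sim_core import BondSpec, DPDParams
from .units import UnitMap, calibrate_unit_map

__all__ = ["ConfigError", "ResolvedConfig", "RunManifest", "load_config"]


class ConfigError(ValueError):
    """A configuration file is malformed or inconsistent."""


_SCHEMA: dict[str, dict[str, Any]] = {
    "box": {"Lx": 10.0, "Ly": 10.0, "h0": 12.0},
    "brush": {
        "chain_lengths": [5, 30, 42],
        "grafting_densities_nm2": [1.76, 0.49, 0.20],
    },
    "walls": {"a_w_tip": 250.0, "z_C": 1.0},
    "dpd": {"a_like": 78.3, "gamma": 4.5, "dt": 0.03, "lam": 0.5, "kT": 1.0, "rho": 3.0},
    "bond": {"model": "fene", "k": 30.0, "length": 1.5},
    "units": {"a_reduced_ref": 150.0, "a_physical_ref_nN": 0.96, "temperature_K": 300.0},
    "schedule": {
        "h_max": 12.0,
        "h_min": 3.0,
        "dh": 0.5,
        "equil_steps": 20000,
        "prod_steps": 50000,
        "sample_every": 100,
        "a_w_values": [150.0, 400.0],
    },
    "seed": 1,
}


@dataclass
class ResolvedConfig:
    """A fully validated configuration with typed sub-objects."""

    raw: dict[str, Any]
    recipe: BrushRecipe
    params: DPDParams
    umap: UnitMap
    schedule: CompressionSchedule
    seed: int

    @property
    def config_hash(self) -> str:
        canon = json.dumps(self.raw, sort_keys=True, default=float)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


@dataclass
class RunManifest:
    """Provenance record attached to every output file."""

    config_hash: str
    seed: int
    code_version: str
    created: str
    parameters: dict[str, Any]

    @classmethod
    def for_config(cls, cfg: ResolvedConfig) -> "RunManifest":
        return cls(
            config_hash=cfg.config_hash,
            seed=cfg.seed,
            code_version=__version__,
            created=time.strftime("%Y-%m-%dT%H:%M:%S"),
            parameters=cfg.raw,
        )

    def to_yaml(self) -> str:
        return yaml.safe_dump(asdict(self), sort_keys=False)

    def header_comment(self) -> str:
        return (
            f"# config_hash = {self.config_hash}\n"
            f"# seed = {self.seed}\n"
            f"# code_version = {self.code_version}\n"
            f"# created = {self.created}"
        )


def _merge_section(name: str, user: dict[str, Any] | None) -> dict[str, Any]:
    defaults = _SCHEMA[name]
    if user is None:
        return dict(defaults)
    if not isinstance(user, dict):
        raise ConfigError(f"section '{name}' must be a mapping")
    unknown = set(user) - set(defaults)
    if unknown:
        raise ConfigError(f"unknown keys in section '{name}': {sorted(unknown)}")
    merged = dict(defaults)
    merged.update(user)
    return merged


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> ResolvedConfig:
    """Load, validate and resolve a YAML config (or pure defaults).

    ``overrides`` (same nested structure) take precedence over the file and
    are validated identically.
    """
    data: dict[str, Any] = {}
    if path is not None:
        text = Path(path).read_text()
        try:
            loaded = yaml.safe_load(text)
        except yaml.YAMLError as exc:
            raise ConfigError(f"cannot parse config file {path}: {exc}") from exc
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ConfigError("config root must be a mapping")
        data = loaded
    if overrides:
        for k, v in overrides.items():
            if isinstance(v, dict) and isinstance(data.get(k), dict):
                data[k] = {**data[k], **v}
            else:
                data[k] = v

    unknown = set(data) - set(_SCHEMA)
    if unknown:
        raise ConfigError(f"unknown top-level keys: {sorted(unknown)}")

    raw: dict[str, Any] = {}
    for name in _SCHEMA:
        if name == "seed":
            seed = data.get("seed", _SCHEMA["seed"])
            if not isinstance(seed, int) or isinstance(seed, bool):
                raise ConfigError("seed must be an integer")
            raw["seed"] = seed
        else:
            raw[name] = _merge_section(name, data.get(name))

    brush = raw["brush"]
    if len(brush["chain_lengths"]) != len(brush["grafting_densities_nm2"]):
        raise ConfigError(
            "brush.chain_lengths and brush.grafting_densities_nm2 must have "
            "the same length"
        )

    u = raw["units"]
    umap = calibrate_unit_map(
        u["a_reduced_ref"], u["a_physical_ref_nN"], u["temperature_K"]
    )
    d = raw["dpd"]
    n_species = len(brush["chain_lengths"]) + 1
    try:
        params = DPDParams.default(
            n_species,
            a_like=d["a_like"],
            gamma=d["gamma"],
            kT=d["kT"],
            dt=d["dt"],
            lam=d["lam"],
            rho=d["rho"],
        )
        bond = BondSpec(**raw["bond"])
    except ValueError as exc:
        raise ConfigError(str(exc)) from exc

    sch = raw["schedule"]
    seps = np.arange(sch["h_max"], sch["h_min"] - 1e-9, -abs(sch["dh"]))
    try:
        schedule = CompressionSchedule(
            separations_rc=seps,
            equil_steps=int(sch["equil_steps"]),
            prod_steps=int(sch["prod_steps"]),
            sample_every=int(sch["sample_every"]),
            a_w_values=[float(a) for a in sch["a_w_values"]],
        )
        recipe = BrushRecipe(
            chain_lengths=[int(n) for n in brush["chain_lengths"]],
            grafting_densities_nm2=[float(g) for g in brush["grafting_densities_nm2"]],
            Lx=float(raw["box"]["Lx"]),
            Ly=float(raw["box"]["Ly"]),
            initial_separation_rc=float(raw["box"]["h0"]),
            a_w_graft=float(schedule.a_w_values[0]),
            a_w_tip=float(raw["walls"]["a_w_tip"]),
            z_C=float(raw["walls"]["z_C"]),
            bond_spec=bond,
        )
    except ValueError as exc:
        raise ConfigError(str(exc)) from exc

    raw["schedule"]["separations_rc"] = [float(x) for x in seps]
    return ResolvedConfig(
        raw=raw,
        recipe=recipe,
        params=params,
        umap=umap,
        schedule=schedule,
        seed=raw["seed"],
    )
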