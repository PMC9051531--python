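"""Seeded fixture generation for tests and demos.

Three kinds are supported:

* ``tiny_brush`` — a minimal polydisperse brush (two chains per population
  in a 5x5 r_c^2 box) that builds and runs fast;
* ``solvent_slab`` — a brush-free slab at the reservoir density;
* ``synthetic_curve`` — a force-compression table generated from the
  exponential brush law b exp(-2 pi h / decay) with optional multiplicative
  Gaussian noise, for exercising the analysis chain without a simulation.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .builder import BrushRecipe, build_system
from .sim_core import DPDParams, State
from .units import UnitMap, calibrate_unit_map
from .xyz import write_trajectory

__all__ = [
    "tiny_brush_recipe",
    "make_tiny_brush",
    "make_solvent_slab",
    "make_synthetic_curve",
    "make_fixture",
]


def _default_umap() -> UnitMap:
    return calibrate_unit_map(150.0, 0.96, 300.0)


def tiny_brush_recipe(umap: UnitMap | None = None) -> BrushRecipe:
    """Two chains per population (lengths 5/8/10) in a 5x5 r_c^2 box.

    Densities are chosen so the count rounds to exactly 2 per population on
    this box through the unit map.
    """
    umap = umap or _default_umap()
    area_nm2 = (5.0 * umap.r_c_nm) ** 2
    g = 2.0 / area_nm2
    return BrushRecipe(
        chain_lengths=[5, 8, 10],
        grafting_densities_nm2=[g, g, g],
        Lx=5.0,
        Ly=5.0,
        initial_separation_rc=8.0,
    )


def make_tiny_brush(seed: int, params: DPDParams | None = None) -> State:
    umap = _default_umap()
    recipe = tiny_brush_recipe(umap)
    params = params or DPDParams.default(len(recipe.chain_lengths) + 1)
    return build_system(recipe, params, umap, seed)


def make_solvent_slab(
    seed: int,
    Lx: float = 5.0,
    Ly: float = 5.0,
    h: float = 8.0,
    params: DPDParams | None = None,
    a_w: float = 150.0,
) -> State:
    umap = _default_umap()
    recipe = BrushRecipe(
        chain_lengths=[1],
        grafting_densities_nm2=[0.0],
        Lx=Lx,
        Ly=Ly,
        initial_separation_rc=h,
        a_w_graft=a_w,
        a_w_tip=a_w,
    )
    params = params or DPDParams.default(2)
    return build_system(recipe, params, umap, seed)


def make_synthetic_curve(
    b: float = 4300.0,
    decay_rc: float = 1.0,
    h_over_decay: np.ndarray | None = None,
    noise: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Synthetic F/R table from the exponential brush law, seeded.

    Returns columns (h_rc, F_over_R); noise is multiplicative Gaussian with
    relative standard deviation ``noise``.
    """
    if h_over_decay is None:
        h_over_decay = np.linspace(0.3, 0.95, 14)
    h = np.asarray(h_over_decay, dtype=float) * decay_rc
    F = b * np.exp(-2.0 * np.pi * h / decay_rc)
    if noise > 0:
        rng = np.random.default_rng(seed)
        F = F * (1.0 + noise * rng.standard_normal(len(F)))
    return pd.DataFrame({"h_rc": h[::-1], "F_over_R": F[::-1]})


def make_fixture(kind: str, seed: int, out_dir: str | Path) -> list[Path]:
    """Write the named fixture to disk; returns the created paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if kind == "tiny_brush":
        state = make_tiny_brush(seed)
        path = out_dir / f"tiny_brush_seed{seed}.xyz"
        write_trajectory(path, [state])
        return [path]
    if kind == "solvent_slab":
        state = make_solvent_slab(seed)
        path = out_dir / f"solvent_slab_seed{seed}.xyz"
        write_trajectory(path, [state])
        return [path]
    if kind == "synthetic_curve":
        df = make_synthetic_curve(seed=seed)
        path = out_dir / f"synthetic_curve_seed{seed}.csv"
        df.to_csv(path, index=False)
        return [path]
    raise ValueError(f"unknown fixture kind: {kind!r}")
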