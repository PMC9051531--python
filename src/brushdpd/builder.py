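"""Assemble initial brush + solvent + walls systems.

A recipe lists chain populations as (polymerization degree, grafting density
in chains/nm^2) pairs; densities are converted to integer chain counts
through the unit map.  Chains start as near-straight lines normal to the
grafting wall with a small seeded lateral jitter, anchors are placed at
z = 0 on random lateral positions subject to a minimum spacing, and solvent
fills the remaining volume to the target bead density.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .sim_core import BondSpec, DPDParams, State, WallSpec
from .units import UnitMap, grafting_density_to_chain_count

__all__ = ["BrushRecipe", "BuildError", "build_system", "MIN_ANCHOR_SPACING"]

#: Minimum lateral distance between two anchors, in r_c.
MIN_ANCHOR_SPACING = 0.5

#: Solvent keeps this distance from either wall at build time, in r_c.
WALL_SKIN = 0.1

#: Default bond spacing along a freshly built chain, in r_c.
CHAIN_SPACING = 0.7


class BuildError(RuntimeError):
    """The requested system cannot be assembled (e.g. anchors too dense)."""


@dataclass
class BrushRecipe:
    """Composition of one polydisperse brush system.

    ``chain_lengths[i]`` beads per chain at ``grafting_densities_nm2[i]``
    chains/nm^2.  The tip wall stiffness ``a_w_tip`` is held fixed across a
    stiffness sweep; ``a_w_graft`` is the grafting-wall stiffness this state
    starts from.
    """

    chain_lengths: Sequence[int]
    grafting_densities_nm2: Sequence[float]
    Lx: float = 10.0
    Ly: float = 10.0
    initial_separation_rc: float = 12.0
    a_w_graft: float = 150.0
    a_w_tip: float = 250.0
    z_C: float = 1.0
    bond_spec: BondSpec = field(default_factory=BondSpec)

    def __post_init__(self) -> None:
        if len(self.chain_lengths) != len(self.grafting_densities_nm2):
            raise ValueError("chain_lengths and grafting_densities_nm2 must match")
        if len(self.chain_lengths) < 1:
            raise ValueError("at least one population required")
        if any(n < 1 for n in self.chain_lengths):
            raise ValueError("chain lengths must be >= 1")
        if any(g < 0 for g in self.grafting_densities_nm2):
            raise ValueError("grafting densities must be non-negative")
        if self.Lx <= 0 or self.Ly <= 0 or self.initial_separation_rc <= 0:
            raise ValueError("box dimensions must be positive")

    def chain_counts(self, umap: UnitMap) -> list[int]:
        area = self.Lx * self.Ly
        return [
            grafting_density_to_chain_count(g, area, umap)
            for g in self.grafting_densities_nm2
        ]


def _place_anchors(
    counts: Sequence[int], Lx: float, Ly: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Random lateral anchor positions with a minimum-spacing constraint.

    Populations are interleaved randomly on the surface.  Raises BuildError
    when the requested anchors cannot be placed at MIN_ANCHOR_SPACING.
    """
    total = int(sum(counts))
    pop = np.concatenate(
        [np.full(c, i, dtype=np.int32) for i, c in enumerate(counts)]
    ) if total else np.zeros(0, dtype=np.int32)
    rng.shuffle(pop)
    placed = np.zeros((total, 2))
    d2min = MIN_ANCHOR_SPACING**2
    max_tries = 2000
    for n in range(total):
        for attempt in range(max_tries):
            x = rng.uniform(0.0, Lx)
            y = rng.uniform(0.0, Ly)
            if n == 0:
                break
            dx = np.abs(placed[:n, 0] - x)
            dy = np.abs(placed[:n, 1] - y)
            dx = np.minimum(dx, Lx - dx)
            dy = np.minimum(dy, Ly - dy)
            if np.min(dx * dx + dy * dy) >= d2min:
                break
        else:
            raise BuildError(
                f"could not place anchor {n + 1}/{total} at minimum spacing "
                f"{MIN_ANCHOR_SPACING} r_c; reduce grafting density or "
                "enlarge the box"
            )
        placed[n] = (x, y)
    return placed, pop


def build_system(
    recipe: BrushRecipe,
    params: DPDParams,
    umap: UnitMap,
    seed: int,
) -> State:
    """Build the initial :class:`State` for a recipe, deterministically.

    Chain counts follow the grafting densities through the unit map; the
    total bead count is round(rho * Lx * Ly * h) with solvent making up the
    difference.  Species codes: 0 = solvent, then one code per population in
    recipe order.
    """
    rng = np.random.default_rng(seed)
    counts = recipe.chain_counts(umap)
    h = recipe.initial_separation_rc
    n_pop = len(recipe.chain_lengths)

    if params.a_matrix.shape[0] < n_pop + 1:
        raise ValueError(
            f"a_matrix covers {params.a_matrix.shape[0]} species but the "
            f"recipe needs {n_pop + 1} (solvent + populations)"
        )

    longest = max(
        (n for n, c in zip(recipe.chain_lengths, counts) if c > 0), default=1
    )
    spacing = CHAIN_SPACING
    if (longest - 1) * spacing > h - 2 * WALL_SKIN:
        warnings.warn(
            f"longest chain ({longest} beads) does not fit unstretched in "
            f"h = {h} r_c; compressing the initial bond spacing",
            stacklevel=2,
        )
        spacing = (h - 2 * WALL_SKIN) / max(1, longest - 1)

    anchors_xy, anchor_pop = _place_anchors(counts, recipe.Lx, recipe.Ly, rng)

    positions: list[np.ndarray] = []
    species: list[np.ndarray] = []
    bonds: list[tuple[int, int]] = []
    anchored: list[np.ndarray] = []

    idx = 0
    for (x, y), p in zip(anchors_xy, anchor_pop):
        n = int(recipe.chain_lengths[p])
        z = np.arange(n) * spacing
        jitter = rng.normal(0.0, 0.1, size=(n, 2))
        jitter[0] = 0.0  # anchor stays where placed
        cx = np.mod(x + jitter[:, 0], recipe.Lx)
        cy = np.mod(y + jitter[:, 1], recipe.Ly)
        chain = np.column_stack([cx, cy, z])
        positions.append(chain)
        species.append(np.full(n, p + 1, dtype=np.int32))
        flags = np.zeros(n, dtype=bool)
        flags[0] = True
        anchored.append(flags)
        bonds.extend((idx + k, idx + k + 1) for k in range(n - 1))
        idx += n

    n_brush = idx
    n_total = int(round(params.rho * recipe.Lx * recipe.Ly * h))
    n_solvent = n_total - n_brush
    if n_solvent < 0:
        raise BuildError(
            f"brush beads ({n_brush}) exceed the bead budget ({n_total}) at "
            f"rho = {params.rho}; enlarge the box or separation"
        )
    if n_solvent > 0:
        sol = np.column_stack(
            [
                rng.uniform(0.0, recipe.Lx, n_solvent),
                rng.uniform(0.0, recipe.Ly, n_solvent),
                rng.uniform(WALL_SKIN, h - WALL_SKIN, n_solvent),
            ]
        )
        positions.append(sol)
        species.append(np.zeros(n_solvent, dtype=np.int32))
        anchored.append(np.zeros(n_solvent, dtype=bool))

    pos = np.vstack(positions) if positions else np.zeros((0, 3))
    spec_arr = np.concatenate(species) if species else np.zeros(0, dtype=np.int32)
    anch = np.concatenate(anchored) if anchored else np.zeros(0, dtype=bool)

    vel = rng.normal(0.0, math.sqrt(params.kT), size=pos.shape)
    vel[anch] = 0.0
    mobile = ~anch
    if mobile.any():  # remove centre-of-mass drift of the mobile beads
        vel[mobile] -= vel[mobile].mean(axis=0)

    names = ["solvent"] + [f"brush{n}" for n in recipe.chain_lengths]
    return State(
        positions=pos,
        velocities=vel,
        species=spec_arr,
        bonds=np.asarray(bonds, dtype=np.int64).reshape(-1, 2),
        bond_spec=recipe.bond_spec,
        Lx=recipe.Lx,
        Ly=recipe.Ly,
        h=h,
        wall_bottom=WallSpec(a_w=recipe.a_w_graft, z_C=recipe.z_C, position=0.0, orientation=1),
        wall_top=WallSpec(a_w=recipe.a_w_tip, z_C=recipe.z_C, position=h, orientation=-1),
        anchored=anch,
        species_names=names,
    )
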