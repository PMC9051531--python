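"""DPD force field, thermostatted integrator and simulation state.

The model is standard dissipative particle dynamics: soft conservative
repulsion a_ij (1 - r/r_c), a pairwise dissipative force -gamma w^2 (e.v) e
and a pairwise random force sigma w theta e / sqrt(dt), with
sigma^2 = 2 gamma kT enforced so the pair thermostat samples the canonical
ensemble.  Chains are bead-spring polymers (finitely extensible bonds by
default, harmonic as an option) grafted to the lower wall; both walls are
soft, linear-ramp force laws F_w(z) = a_w (1 - z/z_C) cut off at z_C.

Integration uses the modified velocity-Verlet scheme with velocity
prediction factor ``lam``.  Anchored (grafted) beads never move but still
exert forces.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from . import _kernels
from ._kernels import (
    BOND_FENE,
    BOND_HARMONIC,
    ERR_BOND_OVEREXTENDED,
    ERR_NONFINITE,
    ERR_OK,
)

__all__ = [
    "DPDParams",
    "WallSpec",
    "BondSpec",
    "State",
    "SampleSet",
    "pair_forces",
    "bond_forces",
    "wall_force",
    "step",
    "simulate",
    "warm_up",
    "kinetic_temperature",
    "BondOverextensionError",
]


class BondOverextensionError(RuntimeError):
    """A finitely extensible bond reached or exceeded its maximum length."""

    def __init__(self, bond_index: int, pair: tuple[int, int]):
        self.bond_index = bond_index
        self.pair = pair
        super().__init__(
            f"bond {bond_index} between beads {pair[0]} and {pair[1]} "
            "is at or beyond its maximum extension"
        )


@dataclass
class DPDParams:
    """Force-field and integrator parameters (reduced units).

    ``a_matrix`` holds the conservative repulsion amplitude per species
    pair; ``sigma`` and ``gamma`` must satisfy fluctuation-dissipation
    (sigma^2 = 2 gamma kT), which is checked at construction.
    """

    a_matrix: np.ndarray
    gamma: float = 4.5
    sigma: float = 3.0
    dt: float = 0.03
    lam: float = 0.5
    kT: float = 1.0
    r_c: float = 1.0
    rho: float = 3.0  # target bead number density, r_c^-3

    def __post_init__(self) -> None:
        self.a_matrix = np.asarray(self.a_matrix, dtype=float)
        if self.a_matrix.ndim != 2 or self.a_matrix.shape[0] != self.a_matrix.shape[1]:
            raise ValueError("a_matrix must be square")
        if not np.allclose(self.a_matrix, self.a_matrix.T):
            raise ValueError("a_matrix must be symmetric")
        if np.any(self.a_matrix < 0):
            raise ValueError("a_matrix entries must be non-negative")
        if not (0.0 < self.dt <= 0.05):
            raise ValueError("dt must satisfy 0 < dt <= 0.05 (stability guard)")
        if self.kT <= 0:
            raise ValueError("kT must be positive")
        fd_gap = abs(self.sigma**2 - 2.0 * self.gamma * self.kT)
        if fd_gap > 1e-10 * max(1.0, self.sigma**2):
            raise ValueError(
                "fluctuation-dissipation violated: need sigma^2 = 2*gamma*kT "
                f"(got sigma^2 = {self.sigma**2:.6g}, 2*gamma*kT = "
                f"{2 * self.gamma * self.kT:.6g})"
            )

    @classmethod
    def default(
        cls,
        n_species: int,
        a_like: float = 78.3,
        gamma: float = 4.5,
        kT: float = 1.0,
        dt: float = 0.03,
        lam: float = 0.5,
        rho: float = 3.0,
    ) -> "DPDParams":
        """Canonical athermal parameter set: all pairs equally repulsive."""
        a = np.full((n_species, n_species), float(a_like))
        return cls(
            a_matrix=a,
            gamma=gamma,
            sigma=math.sqrt(2.0 * gamma * kT),
            dt=dt,
            lam=lam,
            kT=kT,
            rho=rho,
        )


@dataclass(frozen=True)
class WallSpec:
    """Soft wall with force law F_w(z) = a_w (1 - z/z_C), zero beyond z_C.

    ``position`` is the plane's z coordinate; ``orientation`` is +1 if the
    wall repels beads toward larger z (a floor) and -1 for a ceiling.
    """

    a_w: float
    z_C: float = 1.0
    position: float = 0.0
    orientation: int = 1

    def __post_init__(self) -> None:
        if self.a_w <= 0 or self.z_C <= 0:
            raise ValueError("WallSpec requires a_w > 0 and z_C > 0")
        if self.orientation not in (-1, 1):
            raise ValueError("orientation must be +1 or -1")


@dataclass(frozen=True)
class BondSpec:
    """Bead-spring bond parameters shared by all bonds of a system.

    model 'fene': F = -k r / (1 - (r/length)^2) with maximum extension
    ``length`` (no separate hard core; the DPD repulsion keeps beads apart).
    model 'harmonic': F = -k (r - length) about rest length ``length``.
    """

    model: str = "fene"
    k: float = 30.0
    length: float = 1.5

    def __post_init__(self) -> None:
        if self.model not in ("fene", "harmonic"):
            raise ValueError("bond model must be 'fene' or 'harmonic'")
        if self.k <= 0 or self.length < 0:
            raise ValueError("bond k must be > 0 and length >= 0")

    @property
    def code(self) -> int:
        return BOND_FENE if self.model == "fene" else BOND_HARMONIC


@dataclass
class State:
    """All degrees of freedom of one brush-wall system at one instant."""

    positions: np.ndarray  # (N, 3)
    velocities: np.ndarray  # (N, 3)
    species: np.ndarray  # (N,) int32 codes; 0 = solvent
    bonds: np.ndarray  # (M, 2) int64
    bond_spec: BondSpec
    Lx: float
    Ly: float
    h: float
    wall_bottom: WallSpec
    wall_top: WallSpec
    anchored: np.ndarray = field(default=None)  # (N,) bool
    species_names: Sequence[str] = ("S",)

    def __post_init__(self) -> None:
        self.positions = np.ascontiguousarray(self.positions, dtype=float)
        self.velocities = np.ascontiguousarray(self.velocities, dtype=float)
        self.species = np.ascontiguousarray(self.species, dtype=np.int32)
        self.bonds = (
            np.ascontiguousarray(self.bonds, dtype=np.int64)
            if len(self.bonds)
            else np.zeros((0, 2), dtype=np.int64)
        )
        if self.anchored is None:
            self.anchored = np.zeros(self.n_beads, dtype=bool)
        self.anchored = np.ascontiguousarray(self.anchored, dtype=bool)

    @property
    def n_beads(self) -> int:
        return self.positions.shape[0]

    @property
    def mobile(self) -> np.ndarray:
        return ~self.anchored

    @property
    def volume(self) -> float:
        return self.Lx * self.Ly * self.h

    def copy(self) -> "State":
        return State(
            positions=self.positions.copy(),
            velocities=self.velocities.copy(),
            species=self.species.copy(),
            bonds=self.bonds.copy(),
            bond_spec=self.bond_spec,
            Lx=self.Lx,
            Ly=self.Ly,
            h=self.h,
            wall_bottom=self.wall_bottom,
            wall_top=self.wall_top,
            anchored=self.anchored.copy(),
            species_names=tuple(self.species_names),
        )

    def with_graft_stiffness(self, a_w: float) -> "State":
        out = self.copy()
        out.wall_bottom = replace(self.wall_bottom, a_w=float(a_w))
        return out


@dataclass
class SampleSet:
    """Production samples from one run at fixed separation.

    ``frames`` are position snapshots (n_samples, N, 3); the P_zz streams
    hold the instantaneous wall-force pressure on each wall and the virial
    estimate, one entry per sampled step.
    """

    frames: np.ndarray
    species: np.ndarray
    species_names: Sequence[str]
    Lx: float
    Ly: float
    h: float
    temps: np.ndarray
    p_wall_top: np.ndarray
    p_wall_bottom: np.ndarray
    p_virial: np.ndarray
    n_reflected: int = 0

    @property
    def n_samples(self) -> int:
        return len(self.temps)


def _wall_args(state: State) -> tuple[float, float, float, float]:
    wb, wt = state.wall_bottom, state.wall_top
    return wb.a_w, wb.z_C, wt.a_w, wt.z_C


def _raise_on_error(state: State, err: int, err_idx: int) -> None:
    if err == ERR_BOND_OVEREXTENDED:
        i, j = state.bonds[err_idx]
        raise BondOverextensionError(int(err_idx), (int(i), int(j)))
    if err == ERR_NONFINITE:
        raise FloatingPointError(
            f"non-finite coordinate on bead {err_idx}: "
            f"pos={state.positions[err_idx]}, vel={state.velocities[err_idx]}"
        )


def pair_forces(
    state: State,
    params: DPDParams,
    seed: int = 0,
    step_index: int = 0,
    include_random: bool = True,
    include_dissipative: bool = True,
) -> np.ndarray:
    """Total DPD pair force (conservative + dissipative + random) per bead.

    Bond and wall contributions are excluded; see :func:`bond_forces` and
    :func:`wall_force`.  Deterministic for a given (seed, step_index).
    """
    no_bonds = np.zeros((0, 2), dtype=np.int64)
    gamma = params.gamma if include_dissipative else 0.0
    f, *_rest, err, err_idx = _kernels.compute_forces(
        state.positions,
        state.velocities,
        state.species,
        no_bonds,
        state.bond_spec.code,
        state.bond_spec.k,
        state.bond_spec.length,
        params.a_matrix,
        gamma,
        params.sigma,
        1.0 / math.sqrt(params.dt),
        state.Lx,
        state.Ly,
        state.h,
        # walls disabled here by pushing them far outside the slab
        1e-300,
        1e-300,
        1e-300,
        1e-300,
        np.uint64(seed),
        np.uint64(step_index),
        include_random,
    )
    _raise_on_error(state, err, err_idx)
    return f


def bond_forces(state: State) -> np.ndarray:
    """Restoring spring forces along every bond, per bead.

    Action-reaction holds pairwise, so internal bond forces sum to zero.
    Anchored beads receive their share but are held fixed by the integrator.
    """
    zero_a = np.zeros((int(state.species.max()) + 1,) * 2)
    f, *_rest, err, err_idx = _kernels.compute_forces(
        state.positions,
        np.zeros_like(state.velocities),
        state.species,
        state.bonds,
        state.bond_spec.code,
        state.bond_spec.k,
        state.bond_spec.length,
        zero_a,
        0.0,
        0.0,
        1.0,
        state.Lx,
        state.Ly,
        state.h,
        1e-300,
        1e-300,
        1e-300,
        1e-300,
        np.uint64(0),
        np.uint64(0),
        False,
    )
    _raise_on_error(state, err, err_idx)
    return f


def wall_force(z_distance: float, wall: WallSpec) -> float:
    """Scalar repulsive wall force at a distance ``z_distance`` from the plane.

    Negative distances (bead behind the wall) are clamped to contact, so the
    returned force is the finite contact value a_w.
    """
    d = max(0.0, float(z_distance))
    if d >= wall.z_C:
        return 0.0
    return wall.a_w * (1.0 - d / wall.z_C)


def step(
    state: State, params: DPDParams, seed: int = 0, step_index: int = 0
) -> State:
    """Advance one integration step; returns a new State."""
    out = state.copy()
    samples = _run(out, params, n_steps=1, sample_every=0, seed=seed,
                   step0=step_index, store_frames=False)
    del samples
    return out


def _run(
    state: State,
    params: DPDParams,
    n_steps: int,
    sample_every: int,
    seed: int,
    step0: int = 0,
    store_frames: bool = True,
    include_random: bool = True,
) -> SampleSet:
    """Advance ``state`` in place and collect samples."""
    (temps, p_top, p_bot, p_vir, frames, n_s, err, err_idx, n_refl) = _kernels.run_steps(
        state.positions,
        state.velocities,
        state.species,
        state.mobile,
        state.bonds,
        state.bond_spec.code,
        state.bond_spec.k,
        state.bond_spec.length,
        params.a_matrix,
        params.gamma,
        params.sigma,
        params.dt,
        params.lam,
        state.Lx,
        state.Ly,
        state.h,
        *_wall_args(state),
        np.uint64(seed),
        np.uint64(step0),
        int(n_steps),
        int(sample_every),
        include_random,
        store_frames,
    )
    _raise_on_error(state, err, err_idx)
    if not store_frames:
        frames = np.zeros((0, state.n_beads, 3))
    return SampleSet(
        frames=frames[:n_s] if store_frames else frames,
        species=state.species.copy(),
        species_names=tuple(state.species_names),
        Lx=state.Lx,
        Ly=state.Ly,
        h=state.h,
        temps=temps[:n_s],
        p_wall_top=p_top[:n_s],
        p_wall_bottom=p_bot[:n_s],
        p_virial=p_vir[:n_s],
        n_reflected=int(n_refl),
    )


def simulate(
    state: State,
    params: DPDParams,
    n_steps: int,
    sample_every: int = 100,
    seed: int = 0,
    step0: int = 0,
    store_frames: bool = True,
) -> SampleSet:
    """Run thermostatted DPD dynamics, mutating ``state`` in place.

    Returns the production :class:`SampleSet` (kinetic temperature, both
    wall-force P_zz streams, virial P_zz, and position frames).
    """
    if n_steps < 0:
        raise ValueError("n_steps must be non-negative")
    return _run(state, params, n_steps, sample_every, seed, step0, store_frames)


def warm_up(
    state: State,
    params: DPDParams,
    n_steps: int = 500,
    dt_factor: float = 6.0,
    seed: int = 0,
) -> None:
    """Relax a freshly built or just-compressed state at a reduced timestep.

    Random placement can leave near-overlapping beads whose force spikes
    would overextend finitely extensible bonds at the production timestep;
    a short run at dt/dt_factor removes them.  Mutates ``state`` in place.
    """
    import dataclasses

    gentle = dataclasses.replace(params, dt=params.dt / dt_factor)
    _run(state, gentle, n_steps, sample_every=0, seed=seed, store_frames=False)


def kinetic_temperature(state: State) -> float:
    """Instantaneous kinetic temperature sum(m v^2) / (3 N_mobile), m = 1."""
    mobile = state.mobile
    n = int(mobile.sum())
    if n < 1:
        raise ValueError("kinetic temperature requires at least one mobile bead")
    v = state.velocities[mobile]
    return float(np.sum(v * v) / (3.0 * n))
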