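"""The compression experiment.

The tip wall is stepped toward the grafting wall through a decreasing list
of separations.  Constant chemical potential is implemented operationally
as a constant-density solvent reservoir: on each compression step enough
solvent beads are removed to keep the global bead density at the reservoir
value in the shrunken slab.  At every separation the system is equilibrated
and then sampled; the mean and block-averaged SEM of the tip-wall P_zz form
one point of the raw force curve.  The sweep is repeated for each
grafting-wall stiffness with an identical brush (same bead and bond
topology throughout), so stiffness is the only variable.

The whole sweep is deterministic for a given (state, schedule, seed): every
(a_w, separation) stage derives its RNG stream from the master seed by a
fixed splitting rule.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .sim_core import DPDParams, State, simulate, warm_up
from .observables import block_sem

__all__ = [
    "CompressionSchedule",
    "ProtocolError",
    "remove_solvent",
    "run_compression_series",
    "stage_seed",
]

logger = logging.getLogger(__name__)

#: Relative temperature drift beyond which a production run is flagged.
TEMP_DRIFT_TOLERANCE = 0.10

#: Clamp skin for beads left above the new tip position after compression.
CLAMP_SKIN = 0.05


class ProtocolError(RuntimeError):
    """The compression protocol cannot proceed (e.g. out of solvent)."""


@dataclass
class CompressionSchedule:
    """Separations, stage lengths and the stiffness sweep of one experiment."""

    separations_rc: Sequence[float]
    equil_steps: int = 20000
    prod_steps: int = 50000
    sample_every: int = 100
    a_w_values: Sequence[float] = (150.0, 400.0)
    warmup_steps: int = 500

    def __post_init__(self) -> None:
        seps = np.asarray(self.separations_rc, dtype=float)
        if len(seps) < 1 or np.any(seps <= 0):
            raise ValueError("separations must be positive")
        if np.any(np.diff(seps) >= 0):
            raise ValueError("separations must be strictly decreasing")
        if self.prod_steps // self.sample_every < 50:
            raise ValueError(
                "prod_steps/sample_every must be >= 50 (minimum samples for SEM)"
            )
        if any(a <= 0 for a in self.a_w_values):
            raise ValueError("wall stiffnesses must be positive")
        self.separations_rc = seps

    @classmethod
    def default(cls) -> "CompressionSchedule":
        """Desk-scale default: h from 12 down to 3 r_c in 0.5 r_c steps."""
        return cls(separations_rc=np.arange(12.0, 2.9, -0.5))


def stage_seed(master_seed: int, a_w_index: int, h_index: int, phase: int) -> int:
    """Deterministic per-stage stream from one master seed.

    phase 0 = equilibration, 1 = production, 2 = solvent removal.
    """
    return (
        (int(master_seed) * 1_000_003 + a_w_index * 10_007 + h_index * 101 + phase)
        % 2_147_483_647
    )


def remove_solvent(
    state: State, new_h: float, rho_target: float, seed: int = 0
) -> State:
    """Shrink the slab to ``new_h``, removing solvent to keep the density.

    Exactly max(0, N_total - round(rho * Lx * Ly * new_h)) solvent beads are
    removed, drawn uniformly at random (seeded) from the solvent population
    nearest the tip wall (the top half of the solvent by height, always a
    superset of the removal target).  Brush beads are never removed; any
    bead left above the new tip position is clamped just inside the slab.
    """
    if new_h > state.h:
        raise ValueError("remove_solvent only compresses (new_h must be <= h)")
    target = int(round(rho_target * state.Lx * state.Ly * new_h))
    n_remove = max(0, state.n_beads - target)
    solvent = np.flatnonzero(state.species == 0)
    if n_remove > len(solvent):
        raise ProtocolError(
            f"over-compressed: need to remove {n_remove} solvent beads but "
            f"only {len(solvent)} remain"
        )
    keep = np.ones(state.n_beads, dtype=bool)
    if n_remove > 0:
        rng = np.random.default_rng(seed)
        order = solvent[np.argsort(state.positions[solvent, 2])[::-1]]
        pool = order[: max(n_remove, len(order) // 2)]
        chosen = rng.choice(pool, size=n_remove, replace=False)
        keep[chosen] = False

    old_index = np.flatnonzero(keep)
    remap = -np.ones(state.n_beads, dtype=np.int64)
    remap[old_index] = np.arange(len(old_index))
    new_bonds = (
        remap[state.bonds] if len(state.bonds) else state.bonds.copy()
    )
    if len(new_bonds) and np.any(new_bonds < 0):
        raise AssertionError("a bonded (brush) bead was removed")

    out = state.copy()
    out.positions = state.positions[keep]
    out.velocities = state.velocities[keep]
    out.species = state.species[keep]
    out.anchored = state.anchored[keep]
    out.bonds = new_bonds
    out.h = float(new_h)
    from dataclasses import replace as _replace

    out.wall_top = _replace(state.wall_top, position=float(new_h))
    # clamp rule: anything above the new tip sits just inside the slab
    high = out.positions[:, 2] > new_h - CLAMP_SKIN
    out.positions[high, 2] = new_h - CLAMP_SKIN
    return out


def run_compression_series(
    state0: State,
    schedule: CompressionSchedule,
    params: DPDParams,
    seed: int,
    store_frames: bool = False,
    frames_sink=None,
) -> dict[float, pd.DataFrame]:
    """Run the full quasi-static compression sweep for every stiffness.

    Each separation restarts from the previous separation's final
    configuration; each stiffness restarts from the same initial state, so
    brush composition and topology are identical across the sweep.  Returns
    one raw force table per a_w with columns
    (a_w, h_rc, mean_Pzz, sem_Pzz, n_samples, temp_flag).

    ``frames_sink(a_w, h, samples)`` is called with each production
    SampleSet when given (used for density profiles).
    """
    results: dict[float, pd.DataFrame] = {}
    for ia, a_w in enumerate(schedule.a_w_values):
        state = state0.with_graft_stiffness(a_w)
        rows = []
        for ih, h in enumerate(schedule.separations_rc):
            if h > state.h + 1e-9:
                raise ProtocolError(
                    f"schedule separation {h} exceeds current slab height {state.h}"
                )
            if h < state.h - 1e-12:
                state = remove_solvent(
                    state, h, params.rho, seed=stage_seed(seed, ia, ih, 2)
                )
            if schedule.warmup_steps > 0:
                warm_up(
                    state,
                    params,
                    n_steps=schedule.warmup_steps,
                    seed=stage_seed(seed, ia, ih, 3),
                )
            simulate(
                state,
                params,
                schedule.equil_steps,
                sample_every=0,
                seed=stage_seed(seed, ia, ih, 0),
                store_frames=False,
            )
            samples = simulate(
                state,
                params,
                schedule.prod_steps,
                sample_every=schedule.sample_every,
                seed=stage_seed(seed, ia, ih, 1),
                store_frames=store_frames or frames_sink is not None,
            )
            mean_p = float(np.mean(samples.p_wall_top))
            sem_p = block_sem(samples.p_wall_top)
            mean_T = float(np.mean(samples.temps))
            flag = "ok"
            if abs(mean_T - params.kT) > TEMP_DRIFT_TOLERANCE * params.kT:
                flag = "temp_drift"
                logger.warning(
                    "temperature drift at a_w=%s h=%.2f: <T>=%.3f", a_w, h, mean_T
                )
            logger.info(
                "a_w=%s h=%.2f <Pzz>=%.4f +/- %.4f <T>=%.3f",
                a_w, h, mean_p, sem_p, mean_T,
            )
            if frames_sink is not None:
                frames_sink(a_w, h, samples)
            rows.append(
                {
                    "a_w": a_w,
                    "h_rc": h,
                    "mean_Pzz": mean_p,
                    "sem_Pzz": sem_p,
                    "n_samples": samples.n_samples,
                    "mean_T": mean_T,
                    "temp_flag": flag,
                }
            )
        results[float(a_w)] = pd.DataFrame(rows)
    return results
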