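"""Extended-XYZ trajectory output.

One frame per configuration: bead count, a comment line carrying step,
separation, wall stiffness and box, then one ``label x y z`` line per bead.
"""

from __future__ import annotations

from pathlib import Path
from typing import IO

from .sim_core import State

__all__ = ["write_frame", "write_trajectory"]


def write_frame(fh: IO[str], state: State, step: int = 0) -> None:
    fh.write(f"{state.n_beads}\n")
    fh.write(
        f'step={step} h={state.h:.6g} a_w={state.wall_bottom.a_w:.6g} '
        f'Lattice="{state.Lx:.6g} 0 0 0 {state.Ly:.6g} 0 0 0 {state.h:.6g}" '
        f'Properties=species:S:1:pos:R:3\n'
    )
    names = list(state.species_names)
    for i in range(state.n_beads):
        x, y, z = state.positions[i]
        fh.write(f"{names[state.species[i]]} {x:.8f} {y:.8f} {z:.8f}\n")


def write_trajectory(path: str | Path, states, steps=None) -> None:
    """Write a sequence of States as concatenated extended-XYZ frames."""
    states = list(states)
    if steps is None:
        steps = range(len(states))
    with open(path, "w") as fh:
        for s, st in zip(steps, states):
            write_frame(fh, st, step=s)
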