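"""Measurements on sampled trajectories.

Three observables drive the whole analysis chain: binned concentration
profiles along the compression axis, the normal pressure component P_zz
(measured two independent ways, from the force on the tip wall and from the
virial), and the unperturbed brush thickness L derived from the brush
concentration profile's first moment.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .sim_core import SampleSet

__all__ = [
    "DensityProfile",
    "BrushThickness",
    "density_profile",
    "measure_pzz",
    "brush_thickness",
    "block_sem",
]


@dataclass
class DensityProfile:
    """Time-averaged number density per z-bin per species (r_c^-3)."""

    bin_edges: np.ndarray  # (n_bins + 1,)
    rho_per_species: dict[str, np.ndarray]  # name -> (n_bins,)
    frames_used: int
    lateral_area: float

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def bin_width(self) -> float:
        return float(self.bin_edges[1] - self.bin_edges[0])

    def total(self, species: Sequence[str] | None = None) -> np.ndarray:
        """Summed density over the selected species (all by default)."""
        keys = list(self.rho_per_species) if species is None else list(species)
        return np.sum([self.rho_per_species[k] for k in keys], axis=0)

    def restrict(self, species: Sequence[str]) -> "DensityProfile":
        return DensityProfile(
            bin_edges=self.bin_edges,
            rho_per_species={k: self.rho_per_species[k] for k in species},
            frames_used=self.frames_used,
            lateral_area=self.lateral_area,
        )


@dataclass(frozen=True)
class BrushThickness:
    """Unperturbed brush thickness in r_c and the moment formula used."""

    L_rc: float
    definition_tag: str

    def __post_init__(self) -> None:
        if not self.L_rc > 0:
            raise ValueError("brush thickness must be positive")


def block_sem(x: np.ndarray, n_blocks: int = 10) -> float:
    """Standard error of the mean by block averaging.

    Blocks absorb the autocorrelation of the sample stream; with fewer than
    two full blocks, falls back to the naive SEM.
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n < 2:
        return float("nan")
    nb = min(n_blocks, n)
    if nb < 2:
        return float(np.std(x, ddof=1) / np.sqrt(n))
    usable = (n // nb) * nb
    blocks = x[:usable].reshape(nb, -1).mean(axis=1)
    return float(np.std(blocks, ddof=1) / np.sqrt(nb))


def density_profile(
    frames: SampleSet,
    species_filter: Sequence[str] | None = None,
    n_bins: int = 120,
) -> DensityProfile:
    """Time-averaged binned number density along z, per species.

    ``species_filter`` selects which species appear in the result (all by
    default); bins span [0, h].
    """
    if frames.n_samples < 1 or frames.frames.shape[0] < 1:
        raise ValueError("density_profile requires at least one frame")
    if n_bins < 10:
        raise ValueError("n_bins must be >= 10")
    names = list(frames.species_names)
    wanted = names if species_filter is None else list(species_filter)
    unknown = [w for w in wanted if w not in names]
    if unknown:
        raise ValueError(f"unknown species: {unknown}")
    if not wanted:
        raise ValueError("empty species selection")

    edges = np.linspace(0.0, frames.h, n_bins + 1)
    area = frames.Lx * frames.Ly
    bin_vol = area * (edges[1] - edges[0])
    nf = frames.frames.shape[0]
    rho: dict[str, np.ndarray] = {}
    for name in wanted:
        code = names.index(name)
        mask = frames.species == code
        z = frames.frames[:, mask, 2].ravel()
        counts, _ = np.histogram(z, bins=edges)
        rho[name] = counts / (nf * bin_vol)
    return DensityProfile(
        bin_edges=edges, rho_per_species=rho, frames_used=nf, lateral_area=area
    )


def measure_pzz(
    frames: SampleSet, method: str = "wall", n_blocks: int = 10
) -> tuple[float, float]:
    """Mean and SEM of the normal pressure P_zz over production samples.

    method 'wall': time-averaged total z-force the fluid exerts on the tip
    wall divided by the lateral area.  method 'virial':
    (sum m v_z^2 + z-virial)/V with conservative pair, bond and wall
    boundary terms (dissipative/random channels average to zero and are
    excluded).  SEM by block averaging.
    """
    if method == "wall":
        stream = frames.p_wall_top
    elif method == "virial":
        stream = frames.p_virial
    else:
        raise ValueError("method must be 'wall' or 'virial'")
    if len(stream) < 10:
        raise ValueError("measure_pzz needs at least 10 samples")
    return float(np.mean(stream)), block_sem(stream, n_blocks)


def brush_thickness(
    profile: DensityProfile, definition: str = "first_moment_x2"
) -> BrushThickness:
    """Brush thickness from the (brush-only) concentration profile.

    Default: L = 2 <z> = 2 * integral(z rho) / integral(rho), exact for a
    step profile.  'rms' gives sqrt(3) * rms(z), which also recovers H for a
    step profile on [0, H]; 'first_moment' reports plain <z>.
    """
    rho = profile.total()
    z = profile.bin_centers
    norm = float(np.sum(rho))
    if norm <= 0:
        raise ValueError("brush thickness undefined for an all-zero profile")
    mean_z = float(np.sum(z * rho) / norm)
    if definition == "first_moment_x2":
        L = 2.0 * mean_z
    elif definition == "first_moment":
        L = mean_z
    elif definition == "rms":
        L = float(np.sqrt(3.0 * np.sum(z * z * rho) / norm))
    else:
        raise ValueError(f"unknown thickness definition: {definition}")
    return BrushThickness(L_rc=L, definition_tag=definition)
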