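"""Mapping between reduced DPD units and physical units.

DPD works in reduced units where the bead mass, the pair-interaction cutoff
``r_c`` and the thermal energy ``k_B T`` are all 1.  A single anchor point —
one stiffness value known both in reduced force units and in nanonewtons —
fixes the whole linear map, because force in DPD carries units of
``k_B T / r_c``.  From that anchor and the absolute temperature the cutoff
length in nanometres follows, which is what converts grafting densities
quoted in chains/nm^2 into chain counts on a simulation box measured in
``r_c``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "BOLTZMANN_J_PER_K",
    "DEFAULT_TEMPERATURE_K",
    "UnitMap",
    "calibrate_unit_map",
    "grafting_density_to_chain_count",
]

BOLTZMANN_J_PER_K = 1.380649e-23

#: Absolute temperature assumed for calibration when none is given.
DEFAULT_TEMPERATURE_K = 300.0


@dataclass(frozen=True)
class UnitMap:
    """Linear map between reduced DPD units and physical units.

    Attributes
    ----------
    r_c_nm : float
        DPD cutoff length expressed in nanometres.
    kT_J : float
        Thermal energy ``k_B T`` in joules at ``temperature_K``.
    force_scale_nN : float
        One reduced force unit (``k_B T / r_c``) in nanonewtons.
    temperature_K : float
        Absolute temperature in kelvin.
    """

    r_c_nm: float
    kT_J: float
    force_scale_nN: float
    temperature_K: float

    def __post_init__(self) -> None:
        for name in ("r_c_nm", "kT_J", "force_scale_nN", "temperature_K"):
            if not getattr(self, name) > 0.0:
                raise ValueError(f"UnitMap.{name} must be strictly positive")
        # force_scale must be consistent with kT / r_c (J/nm -> nN is 1e9*1e9)
        implied = self.kT_J / self.r_c_nm * 1e18
        if abs(implied - self.force_scale_nN) > 1e-9 * self.force_scale_nN:
            raise ValueError(
                "inconsistent UnitMap: force_scale_nN != kT_J / r_c_nm"
            )

    # -- force conversions -------------------------------------------------
    def reduced_to_physical_force_nN(self, f_reduced: float) -> float:
        """Convert a reduced force (units of kT/r_c) to nanonewtons."""
        return f_reduced * self.force_scale_nN

    def physical_to_reduced_force(self, f_nN: float) -> float:
        """Convert a force in nanonewtons to reduced units."""
        return f_nN / self.force_scale_nN

    # -- length conversions ------------------------------------------------
    def reduced_to_physical_length_nm(self, x_rc: float) -> float:
        return x_rc * self.r_c_nm

    def physical_to_reduced_length(self, x_nm: float) -> float:
        return x_nm / self.r_c_nm

    def header_block(self) -> str:
        """Plain key-value block for embedding in output-file comments."""
        lines = [
            f"# r_c_nm = {self.r_c_nm:.6g}",
            f"# kT_J = {self.kT_J:.6g}",
            f"# force_scale_nN = {self.force_scale_nN:.6g}",
            f"# temperature_K = {self.temperature_K:.6g}",
        ]
        return "\n".join(lines)


def calibrate_unit_map(
    a_reduced_ref: float,
    a_physical_ref_nN: float,
    temperature_K: float = DEFAULT_TEMPERATURE_K,
) -> UnitMap:
    """Build a :class:`UnitMap` from one stiffness anchor.

    Parameters
    ----------
    a_reduced_ref : float
        A wall stiffness in reduced DPD force units.
    a_physical_ref_nN : float
        The same stiffness in nanonewtons.
    temperature_K : float
        Absolute temperature; defaults to 300 K.

    Returns
    -------
    UnitMap
        With ``force_scale_nN = a_physical_ref_nN / a_reduced_ref`` and the
        cutoff length back-derived from ``r_c = k_B T / (force scale)``.
    """
    if not (a_reduced_ref > 0 and a_physical_ref_nN > 0 and temperature_K > 0):
        raise ValueError("calibrate_unit_map requires strictly positive arguments")
    force_scale_nN = a_physical_ref_nN / a_reduced_ref
    kT_J = BOLTZMANN_J_PER_K * temperature_K
    # nN * nm = 1e-18 J, hence r_c[nm] = kT[J] / (force[nN] * 1e-18)
    r_c_nm = kT_J / (force_scale_nN * 1e-18)
    return UnitMap(
        r_c_nm=r_c_nm,
        kT_J=kT_J,
        force_scale_nN=force_scale_nN,
        temperature_K=temperature_K,
    )


def grafting_density_to_chain_count(
    gamma_nm2: float, lateral_area_rc2: float, umap: UnitMap
) -> int:
    """Number of grafted chains for a density in chains/nm^2 on an area in r_c^2.

    Rounds half-up so builder populations are deterministic.
    """
    if gamma_nm2 < 0:
        raise ValueError("grafting density must be non-negative")
    if lateral_area_rc2 <= 0:
        raise ValueError("lateral area must be positive")
    exact = gamma_nm2 * umap.r_c_nm**2 * lateral_area_rc2
    return int(math.floor(exact + 0.5))
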