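"""From raw P_zz(h) tables to Derjaguin force profiles and brush-law fits.

The chain is: subtract the uncompressed-system bulk pressure to get the
disjoining pressure Pi(h) = P_zz(h) - P_B; integrate it with the Derjaguin
approximation, F/R(h) = 2 pi * integral_h^{h_max} Pi(h') dh', to obtain the
force per probe radius an AFM with a large tip would measure; split the
profile into the strong (h/L < 1) and weak (1 <= h/L <= 2) compression
regimes; fit each with the Alexander-de Gennes exponential
b * exp(-2 pi h / L_decay) with the decay fixed (L in the strong regime,
L' = 3.3 L in the weak one) and b the single free amplitude; and finally
form the stiffness ratio r = b_hard / b_soft, which is indentation
independent because both profiles share the exponential factor.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd

__all__ = [
    "ForceCurve",
    "AdGFit",
    "WEAK_DECAY_FACTOR",
    "disjoining_pressure",
    "derjaguin_force",
    "adg_pressure",
    "split_regimes",
    "fit_force_exponential",
    "stiffness_ratio",
    "force_curve_from_pzz",
    "load_force_table",
]

#: Decay length of the weak-compression fit in units of L (L' = 3.3 L).
WEAK_DECAY_FACTOR = 3.3


@dataclass
class ForceCurve:
    """Force-compression data for one grafting-wall stiffness.

    Separations are stored decreasing; ``Pi`` and ``F_over_R`` are filled by
    :func:`disjoining_pressure` and :func:`derjaguin_force`.  ``F_over_R``
    is dimensionless (units of kT / r_c^2) in reduced DPD units.
    """

    h_rc: np.ndarray
    Pzz: np.ndarray
    sem_Pzz: np.ndarray | None = None
    a_w: float | None = None
    L_rc: float | None = None
    Pi: np.ndarray | None = None
    sem_Pi: np.ndarray | None = None
    F_over_R: np.ndarray | None = None
    sem_F_over_R: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.h_rc = np.asarray(self.h_rc, dtype=float)
        self.Pzz = np.asarray(self.Pzz, dtype=float)
        if self.h_rc.shape != self.Pzz.shape:
            raise ValueError("h_rc and Pzz must have the same shape")
        if np.any(np.diff(self.h_rc) >= 0):
            order = np.argsort(self.h_rc)[::-1]
            self.h_rc = self.h_rc[order]
            self.Pzz = self.Pzz[order]
            if self.sem_Pzz is not None:
                self.sem_Pzz = np.asarray(self.sem_Pzz, dtype=float)[order]
        if self.sem_Pzz is not None:
            self.sem_Pzz = np.asarray(self.sem_Pzz, dtype=float)

    @property
    def h_over_L(self) -> np.ndarray:
        if self.L_rc is None:
            raise ValueError("L_rc not set on this curve")
        return self.h_rc / self.L_rc

    @property
    def h_max(self) -> float:
        return float(self.h_rc[0])

    def to_frame(self) -> pd.DataFrame:
        data: dict[str, np.ndarray | float] = {"h_rc": self.h_rc, "Pzz": self.Pzz}
        if self.sem_Pzz is not None:
            data["sem_Pzz"] = self.sem_Pzz
        if self.L_rc is not None:
            data["h_over_L"] = self.h_over_L
        if self.Pi is not None:
            data["Pi"] = self.Pi
        if self.sem_Pi is not None:
            data["sem_Pi"] = self.sem_Pi
        if self.F_over_R is not None:
            data["F_over_R"] = self.F_over_R
        if self.sem_F_over_R is not None:
            data["sem_F_over_R"] = self.sem_F_over_R
        df = pd.DataFrame(data)
        if self.a_w is not None:
            df.insert(0, "a_w", self.a_w)
        return df


@dataclass(frozen=True)
class AdGFit:
    """One-parameter fit of F/R = b exp(-2 pi h / decay_length)."""

    b: float
    decay_length_rc: float
    regime: Literal["strong", "weak"]
    rss: float
    n_points: int
    sem_b: float = field(default=float("nan"))

    def __post_init__(self) -> None:
        if not self.b > 0:
            raise ValueError("fitted amplitude b must be positive")
        if self.n_points < 3:
            raise ValueError("an AdG fit needs at least 3 points")

    def predict(self, h_rc: np.ndarray) -> np.ndarray:
        return self.b * np.exp(-2.0 * np.pi * np.asarray(h_rc) / self.decay_length_rc)


def force_curve_from_pzz(
    df: pd.DataFrame, a_w: float | None = None, L_rc: float | None = None
) -> ForceCurve:
    """Build a raw ForceCurve from a (h_rc, mean_Pzz[, sem_Pzz]) table."""
    sem = df["sem_Pzz"].to_numpy() if "sem_Pzz" in df else None
    return ForceCurve(
        h_rc=df["h_rc"].to_numpy(),
        Pzz=df["mean_Pzz"].to_numpy() if "mean_Pzz" in df else df["Pzz"].to_numpy(),
        sem_Pzz=sem,
        a_w=a_w if a_w is not None else (float(df["a_w"].iloc[0]) if "a_w" in df else None),
        L_rc=L_rc,
    )


def load_force_table(path) -> dict[float, ForceCurve]:
    """Read a CSV of raw P_zz data, one ForceCurve per a_w value.

    Accepts columns (a_w, h_rc, mean_Pzz[, sem_Pzz]); comment lines
    starting with '#' are ignored.
    """
    df = pd.read_csv(path, comment="#")
    if "a_w" not in df:
        df["a_w"] = np.nan
    out: dict[float, ForceCurve] = {}
    for a_w, sub in df.groupby("a_w", dropna=False):
        key = float(a_w)
        out[key] = force_curve_from_pzz(sub.reset_index(drop=True), a_w=key)
    return out


def disjoining_pressure(
    curve: ForceCurve, P_B: float, sem_P_B: float = 0.0
) -> ForceCurve:
    """Fill Pi = P_zz - P_B on the curve (SEMs add in quadrature).

    By construction Pi vanishes at the widest separation when P_B is taken
    there, which is how the protocol defines the bulk reference.
    """
    if not np.isfinite(P_B):
        raise ValueError("P_B must be finite")
    curve.Pi = curve.Pzz - P_B
    if curve.sem_Pzz is not None:
        curve.sem_Pi = np.sqrt(curve.sem_Pzz**2 + sem_P_B**2)
    return curve


def derjaguin_force(curve: ForceCurve) -> ForceCurve:
    """Fill F/R(h) = 2 pi * integral_h^{h_max} Pi dh' by the trapezoid rule.

    The 2 pi prefactor is the sphere-plane Derjaguin convention; it cancels
    in every amplitude ratio.  The widest point gets exactly 0 (empty
    integral).
    """
    if curve.Pi is None:
        raise ValueError("run disjoining_pressure first")
    h = curve.h_rc
    if len(h) < 2:
        raise ValueError("derjaguin_force needs at least 2 points")
    # h decreasing: integral from h_i up to h_max accumulates from the left
    dh = h[:-1] - h[1:]
    seg = 0.5 * (curve.Pi[:-1] + curve.Pi[1:]) * dh
    F = 2.0 * np.pi * np.concatenate([[0.0], np.cumsum(seg)])
    curve.F_over_R = F
    if curve.sem_Pi is not None:
        # trapezoid weights: w_0 = dh_0/2, w_i = (dh_{i-1}+dh_i)/2, w_last = dh_last/2
        var = np.zeros_like(F)
        for i in range(1, len(h)):
            wloc = np.zeros(i + 1)
            wloc[0] = 0.5 * dh[0]
            for k in range(1, i):
                wloc[k] = 0.5 * (dh[k - 1] + dh[k])
            wloc[i] = 0.5 * dh[i - 1]
            var[i] = np.sum((wloc * curve.sem_Pi[: i + 1]) ** 2)
        curve.sem_F_over_R = 2.0 * np.pi * np.sqrt(var)
    return curve


def adg_pressure(
    h_over_L: np.ndarray | float,
    Gamma: float = 1.0,
    kT: float = 1.0,
    form: str = "exact",
) -> np.ndarray | float:
    """Alexander-de Gennes pressure between a brush and a compressing plane.

    form 'exact': Gamma^{3/2} kT [(L/h)^{9/4} - (h/L)^{3/4}], valid for
    h/L < 1 (a warning is issued outside that range, where the expression
    goes negative).  form 'exponential': 100 Gamma^{3/2} kT e^{-2 pi h/L},
    the standard intermediate-compression approximation.
    """
    x = np.asarray(h_over_L, dtype=float)
    scalar = x.ndim == 0
    x = np.atleast_1d(x)
    if np.any(x <= 0):
        raise ValueError("h_over_L must be positive")
    amp = Gamma**1.5 * kT
    if form == "exact":
        if np.any(x >= 1):
            warnings.warn(
                "exact AdG form applies for h/L < 1; values at h/L >= 1 are "
                "extrapolations",
                stacklevel=2,
            )
        out = amp * (x ** -2.25 - x**0.75)
    elif form == "exponential":
        out = 100.0 * amp * np.exp(-2.0 * np.pi * x)
    else:
        raise ValueError("form must be 'exact' or 'exponential'")
    return float(out[0]) if scalar else out


def split_regimes(
    curve: ForceCurve, L_rc: float | None = None
) -> tuple[ForceCurve, ForceCurve]:
    """Split a curve into strong (h/L < 1) and weak (1 <= h/L <= 2) segments.

    The boundary point h/L = 1 belongs to the weak segment (the weak range
    is the closed interval [1, 2]).  Segments with fewer than 3 points are
    returned but flagged unusable by the fitter.
    """
    L = L_rc if L_rc is not None else curve.L_rc
    if L is None or L <= 0:
        raise ValueError("a positive brush thickness L is required")
    x = curve.h_rc / L

    def _take(mask: np.ndarray) -> ForceCurve:
        sub = ForceCurve(
            h_rc=curve.h_rc[mask],
            Pzz=curve.Pzz[mask],
            sem_Pzz=None if curve.sem_Pzz is None else curve.sem_Pzz[mask],
            a_w=curve.a_w,
            L_rc=L,
        )
        if curve.Pi is not None:
            sub.Pi = curve.Pi[mask]
        if curve.sem_Pi is not None:
            sub.sem_Pi = curve.sem_Pi[mask]
        if curve.F_over_R is not None:
            sub.F_over_R = curve.F_over_R[mask]
        if curve.sem_F_over_R is not None:
            sub.sem_F_over_R = curve.sem_F_over_R[mask]
        return sub

    strong = _take(x < 1.0)
    weak = _take((x >= 1.0) & (x <= 2.0))
    return strong, weak


def fit_force_exponential(
    segment: ForceCurve, decay_length_rc: float, regime: str = "strong"
) -> AdGFit:
    """Least-squares fit of F/R = b exp(-2 pi h / decay) over b alone.

    The decay length is fixed (L for the strong regime, 3.3 L for the weak
    one); points with non-positive force are excluded with a warning.
    Inverse-variance weights are used when SEMs are available.
    """
    if segment.F_over_R is None:
        raise ValueError("segment has no F/R values; run derjaguin_force first")
    if decay_length_rc <= 0:
        raise ValueError("decay length must be positive")
    y = segment.F_over_R
    h = segment.h_rc
    sem = segment.sem_F_over_R
    keep = y > 0
    if not np.all(keep):
        warnings.warn(
            f"excluding {int(np.sum(~keep))} non-positive force points from "
            "the exponential fit",
            stacklevel=2,
        )
    h, y = h[keep], y[keep]
    if sem is not None:
        sem = sem[keep]
    if len(y) < 3:
        raise ValueError("fit requires at least 3 usable points")
    x = np.exp(-2.0 * np.pi * h / decay_length_rc)
    if sem is not None and np.all(np.isfinite(sem)) and np.all(sem > 0):
        w = 1.0 / sem**2
    else:
        w = np.ones_like(y)
    b = float(np.sum(w * x * y) / np.sum(w * x * x))
    resid = y - b * x
    rss = float(np.sum(resid**2))
    # amplitude uncertainty from weighted linear regression through origin
    if len(y) > 1:
        dof = len(y) - 1
        sem_b = float(np.sqrt(np.sum(w * resid**2) / dof / np.sum(w * x * x)))
    else:
        sem_b = float("nan")
    return AdGFit(
        b=b,
        decay_length_rc=float(decay_length_rc),
        regime=regime,  # type: ignore[arg-type]
        rss=rss,
        n_points=int(len(y)),
        sem_b=sem_b,
    )


def stiffness_ratio(fit_hard: AdGFit, fit_soft: AdGFit) -> float:
    """Ratio r = b_hard / b_soft of fitted force amplitudes.

    Both fits must come from the same regime with the same fixed decay, so
    the exponential factors cancel and r equals the force ratio at every
    separation — the indentation-independent stiffness statistic.
    """
    if fit_hard.regime != fit_soft.regime:
        raise ValueError("fits compare different compression regimes")
    if not np.isclose(fit_hard.decay_length_rc, fit_soft.decay_length_rc):
        raise ValueError("fits use different decay lengths")
    return fit_hard.b / fit_soft.b
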