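"""Pair-interaction laws for the electrosolvation problem.

The central object is the two-exponential potential

    U(x) = A exp(-κ₁ x) + B exp(-κ₂ x),        κ₂ < κ₁ ≈ κ,

acting between the *surfaces* of two spheres at surface separation ``x``.
The first term is the familiar screened electrostatic repulsion (A ≥ 0,
κ₁⁻¹ the Debye length); the second carries the interfacial-solvation
contribution whose amplitude B ∝ z·μ_av may take either sign.  For B < 0 the
potential has a single long-ranged minimum of depth ``w`` at ``x_min``; the
(w, x_min) ↔ (A, B) map is closed-form in both directions.

Energies are in units of k_B T, lengths in μm, so κ values are in μm⁻¹.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from typing import Literal, Optional, Tuple

import numpy as np

from .media import BOLTZMANN, UM_TO_M, ZJ_TO_J

__all__ = [
    "ElectrosolvationPotential", "WellSpec", "VdwModel",
    "potential_from_well", "well_parameters", "vdw_energy",
    "attraction_expected",
]


@dataclass(frozen=True)
class ElectrosolvationPotential:
    """U(x) = A e^{-κ₁x} + B e^{-κ₂x} with A in k_BT, κ in μm⁻¹."""

    A: float
    B: float
    kappa1: float
    kappa2: float

    def __post_init__(self) -> None:
        if self.A < 0:
            raise ValueError(f"repulsive amplitude A must be >= 0, got {self.A}")
        if self.kappa1 <= 0 or self.kappa2 <= 0:
            raise ValueError("screening parameters must be positive")
        if not (self.A == 0.0 and self.B == 0.0) and self.kappa2 >= self.kappa1:
            raise ValueError(
                f"kappa2 must be < kappa1 (got kappa1={self.kappa1}, "
                f"kappa2={self.kappa2})"
            )

    # -- evaluation ---------------------------------------------------------
    def evaluate(self, x):
        """Energy U(x) in k_BT at surface separation x ≥ 0 (μm)."""
        x = np.asarray(x, dtype=float)
        if np.any(x < 0):
            raise ValueError("surface separation x must be non-negative")
        out = self.A * np.exp(-self.kappa1 * x) + self.B * np.exp(-self.kappa2 * x)
        return float(out) if out.ndim == 0 else out

    __call__ = evaluate

    def force(self, x):
        """-dU/dx in k_BT μm⁻¹ (positive = repulsive, pushing surfaces apart)."""
        x = np.asarray(x, dtype=float)
        if np.any(x < 0):
            raise ValueError("surface separation x must be non-negative")
        out = (self.A * self.kappa1 * np.exp(-self.kappa1 * x)
               + self.B * self.kappa2 * np.exp(-self.kappa2 * x))
        return float(out) if out.ndim == 0 else out

    @property
    def is_null(self) -> bool:
        return self.A == 0.0 and self.B == 0.0

    def cutoff(self, tol: float = 1e-3) -> float:
        """Surface separation beyond which |U| < tol k_BT (conservative bound
        obtained from each exponential term separately)."""
        if self.is_null:
            return 0.0
        xs = []
        if self.A > 0:
            xs.append(math.log(2.0 * self.A / tol) / self.kappa1)
        if self.B != 0.0:
            xs.append(math.log(2.0 * abs(self.B) / tol) / self.kappa2)
        return max(0.0, *xs)

    # -- serialization ------------------------------------------------------
    def to_dict(self) -> dict:
        return {"format_version": 1, "A_kBT": self.A, "B_kBT": self.B,
                "kappa1_per_um": self.kappa1, "kappa2_per_um": self.kappa2}

    @classmethod
    def from_dict(cls, d: dict) -> "ElectrosolvationPotential":
        return cls(A=float(d["A_kBT"]), B=float(d["B_kBT"]),
                   kappa1=float(d["kappa1_per_um"]), kappa2=float(d["kappa2_per_um"]))

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def from_json(cls, path: str) -> "ElectrosolvationPotential":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    def tabulate(self, x_max: float, n: int = 500) -> np.ndarray:
        """(n, 2) array of (x_um, U_kBT) on a uniform grid [0, x_max]."""
        x = np.linspace(0.0, x_max, n)
        return np.column_stack([x, self.evaluate(x)])


NULL_POTENTIAL = ElectrosolvationPotential(A=0.0, B=0.0, kappa1=1.0, kappa2=0.5)


@dataclass(frozen=True)
class WellSpec:
    """A potential specified by its minimum: depth w (k_BT, ≤ 0) at x_min (μm),
    with κ₁ (μm⁻¹) and the fixed ratio κ₂/κ₁ (default 0.95)."""

    w: float
    x_min: float
    kappa1: float
    kappa_ratio: float = 0.95

    def __post_init__(self) -> None:
        if self.x_min <= 0:
            raise ValueError(f"x_min must be positive, got {self.x_min}")
        if not (0.0 < self.kappa_ratio < 1.0):
            raise ValueError(
                f"kappa_ratio must lie strictly in (0, 1), got {self.kappa_ratio}; "
                "kappa2 -> kappa1 makes the A,B construction degenerate"
            )
        if self.kappa1 <= 0:
            raise ValueError(f"kappa1 must be positive, got {self.kappa1}")
        if self.w > 0:
            raise ValueError(f"well depth w must be <= 0, got {self.w}")


def potential_from_well(spec: WellSpec) -> ElectrosolvationPotential:
    """Construct the (A, B) amplitudes that place the minimum at (w, x_min):

        A = -w κ₂ e^{κ₁ x_min} / (κ₁ - κ₂)
        B =  w κ₁ e^{κ₂ x_min} / (κ₁ - κ₂)

    so that U(x_min) = w and U'(x_min) = 0 identically.  w = 0 yields the
    null potential.
    """
    k1 = spec.kappa1
    k2 = spec.kappa_ratio * k1
    if spec.w == 0.0:
        return ElectrosolvationPotential(A=0.0, B=0.0, kappa1=k1, kappa2=k2)
    dk = k1 - k2
    A = -spec.w * k2 * math.exp(k1 * spec.x_min) / dk
    B = spec.w * k1 * math.exp(k2 * spec.x_min) / dk
    return ElectrosolvationPotential(A=A, B=B, kappa1=k1, kappa2=k2)


def well_parameters(potential: ElectrosolvationPotential
                    ) -> Optional[Tuple[float, float]]:
    """Invert the well construction: return (w, x_min) of the interior minimum,
    or None when B ≥ 0 (monotone, purely repulsive potential)."""
    if potential.B >= 0.0:
        return None
    x_min = (math.log(potential.A * potential.kappa1
                      / (-potential.B * potential.kappa2))
             / (potential.kappa1 - potential.kappa2))
    w = potential.evaluate(max(x_min, 0.0))
    return float(w), float(x_min)


@dataclass(frozen=True)
class VdwModel:
    """Sphere–sphere van der Waals attraction in the Derjaguin–Hamaker limit.

    U(x) = -A_H R_eff / (6 x) with R_eff = R₁R₂/(R₁+R₂); with
    ``retardation_wavelength_nm`` set, the Gregory screening factor
    1/(1 + 14 x/λ) multiplies the energy.  Both are standard textbook
    approximations for x ≪ R.
    """

    hamaker_zJ: float
    radius1_um: float
    radius2_um: float
    retardation_wavelength_nm: Optional[float] = None
    temperature_K: float = 298.0

    def __post_init__(self) -> None:
        if self.hamaker_zJ < 0:
            raise ValueError(f"hamaker_zJ must be >= 0, got {self.hamaker_zJ}")
        if self.radius1_um <= 0 or self.radius2_um <= 0:
            raise ValueError("radii must be positive")

    @property
    def effective_radius_um(self) -> float:
        return (self.radius1_um * self.radius2_um
                / (self.radius1_um + self.radius2_um))


def vdw_energy(model: VdwModel, x_um) -> "np.ndarray | float":
    """vdW energy in k_BT at surface separation x > 0 (μm); always ≤ 0."""
    x = np.asarray(x_um, dtype=float)
    if np.any(x <= 0):
        raise ValueError("vdw_energy diverges at x <= 0; x must be positive")
    kBT = BOLTZMANN * model.temperature_K
    u_joule = -(model.hamaker_zJ * ZJ_TO_J) * (
        model.effective_radius_um * UM_TO_M) / (6.0 * x * UM_TO_M)
    u = u_joule / kBT
    if model.retardation_wavelength_nm is not None:
        lam_um = model.retardation_wavelength_nm * 1e-3
        u = u / (1.0 + 14.0 * x / lam_um)
    return float(u) if u.ndim == 0 else u


def attraction_expected(z_sign: int, mu_av: float,
                        marginal_threshold: float = 0.15,
                        ) -> Literal["attract", "repel", "marginal"]:
    """Quadrant rule for the sign of the interfacial term: B ∝ z·μ_av.

    Attraction between like-charged particles requires B < 0, i.e. the sign
    of the particle charge ``z_sign`` opposite to the sign of the excess
    interfacial dipole density ``mu_av`` (D nm⁻²).  Magnitudes below
    ``marginal_threshold`` are classed "marginal": too weak an interfacial
    dipole density to support a substantial attractive force.
    """
    if z_sign not in (-1, 1):
        raise ValueError(f"z_sign must be -1 or +1, got {z_sign}")
    if marginal_threshold < 0:
        raise ValueError("marginal_threshold must be >= 0")
    prod = z_sign * mu_av
    if prod < -marginal_threshold:
        return "attract"
    if prod > marginal_threshold:
        return "repel"
    return "marginal"
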