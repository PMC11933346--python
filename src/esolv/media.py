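"""Electrolyte media: physical constants, Debye screening and conductivity
calibration.

All unit conversions between the practical units used in the colloid modules
(cP, Å, μS cm⁻¹, mM, μm, Debye) and SI live here, so that every other module
works with a single, checked conversion site.

Energies elsewhere in the package are expressed in units of ``k_B T``; the
absolute temperature enters through a :class:`Medium`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from typing import Optional

import yaml

# ---------------------------------------------------------------------------
# Physical constants (CODATA 2018, exact where the SI defines them so)
# ---------------------------------------------------------------------------
ELEMENTARY_CHARGE = 1.602176634e-19  # C (exact)
BOLTZMANN = 1.380649e-23  # J/K (exact)
AVOGADRO = 6.02214076e23  # 1/mol (exact)
VACUUM_PERMITTIVITY = 8.8541878128e-12  # F/m
DEBYE = 3.33564095198152e-30  # C·m per Debye unit

# unit conversion factors
CP_TO_PA_S = 1.0e-3  # centipoise -> Pa·s
ANGSTROM_TO_M = 1.0e-10
NM_TO_M = 1.0e-9
UM_TO_M = 1.0e-6
MM_TO_MOL_M3 = 1.0  # 1 mM == 1 mol/m^3
ZJ_TO_J = 1.0e-21


def thermal_energy(temperature_K: float) -> float:
    """k_B T in joules."""
    if temperature_K <= 0:
        raise ValueError(f"temperature must be positive, got {temperature_K} K")
    return BOLTZMANN * temperature_K


# ---------------------------------------------------------------------------
# Media
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Medium:
    """A solvent/electrolyte phase.

    Parameters
    ----------
    name:
        Free-text label ("water", "2-propanol", ...).
    relative_permittivity:
        Static dielectric constant ε_r (> 1).
    viscosity_cP:
        Dynamic viscosity η in centipoise.
    temperature_K:
        Absolute temperature.
    ionic_strength_mM:
        Monovalent-equivalent salt concentration c₀ in mM.
    pH, zeta_potential_mV:
        Optional metadata; ζ is used only to establish the *sign* of the
        particle charge and never enters a computation here.
    """

    name: str
    relative_permittivity: float
    viscosity_cP: float
    temperature_K: float = 298.0
    ionic_strength_mM: float = 0.0
    pH: Optional[float] = None
    zeta_potential_mV: Optional[float] = None
    notes: str = ""

    def __post_init__(self) -> None:
        if self.relative_permittivity <= 1:
            raise ValueError(
                f"relative_permittivity must exceed 1, got {self.relative_permittivity}"
            )
        if self.viscosity_cP <= 0:
            raise ValueError(f"viscosity_cP must be positive, got {self.viscosity_cP}")
        if self.temperature_K <= 0:
            raise ValueError(f"temperature_K must be positive, got {self.temperature_K}")
        if self.ionic_strength_mM < 0:
            raise ValueError(
                f"ionic_strength_mM must be non-negative, got {self.ionic_strength_mM}"
            )

    @property
    def ion_number_density_m3(self) -> float:
        """Number density of monovalent ions of one sign, ρ_ion (1/m³)."""
        return self.ionic_strength_mM * MM_TO_MOL_M3 * AVOGADRO


#: Water at 298 K; η is the standard 0.89 cP value, ε_r the common 78.4.
WATER = Medium(name="water", relative_permittivity=78.4, viscosity_cP=0.89,
               temperature_K=298.0, ionic_strength_mM=0.1)


def debye_length_nm(medium: Medium) -> float:
    """Debye screening length κ⁻¹ = sqrt(ε₀ ε_r k_B T / (2 ρ_ion e²)) in nm.

    The electrical potential around a charged object in an electrolyte of
    monovalent-ion number density ρ_ion decays exponentially with this
    characteristic length.  Scales as ionic_strength^(−1/2).
    """
    if medium.ionic_strength_mM <= 0:
        raise ValueError(
            "debye_length requires ionic_strength_mM > 0 "
            f"(got {medium.ionic_strength_mM})"
        )
    num = (VACUUM_PERMITTIVITY * medium.relative_permittivity
           * thermal_energy(medium.temperature_K))
    den = 2.0 * medium.ion_number_density_m3 * ELEMENTARY_CHARGE ** 2
    return math.sqrt(num / den) / NM_TO_M


def ionic_strength_for_debye_length(medium: Medium, kappa_inv_nm: float) -> float:
    """Inverse of :func:`debye_length_nm`: the ionic strength (mM) that yields
    the given screening length in this medium."""
    if kappa_inv_nm <= 0:
        raise ValueError(f"kappa_inv_nm must be positive, got {kappa_inv_nm}")
    num = (VACUUM_PERMITTIVITY * medium.relative_permittivity
           * thermal_energy(medium.temperature_K))
    rho = num / (2.0 * ELEMENTARY_CHARGE ** 2 * (kappa_inv_nm * NM_TO_M) ** 2)
    return rho / (AVOGADRO * MM_TO_MOL_M3)


# ---------------------------------------------------------------------------
# Conductivity <-> ionic strength calibration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CalibrationCurve:
    """Linear conductivity calibration s = a·c₀ for 1:1 electrolytes.

    ``slope_a`` is in μS cm⁻¹ per mM; ``reference_viscosity_cP`` is the
    viscosity of the solvent in which the calibration was established
    (water for the standard-solution curve).
    """

    slope_a: float
    reference_viscosity_cP: float = 0.89
    source: str = "measured"

    def __post_init__(self) -> None:
        if self.slope_a <= 0:
            raise ValueError(f"slope_a must be positive, got {self.slope_a}")
        if self.reference_viscosity_cP <= 0:
            raise ValueError(
                f"reference_viscosity_cP must be positive, got {self.reference_viscosity_cP}"
            )


#: Experimentally determined standard-solution calibration slope in water.
MEASURED_CALIBRATION = CalibrationCurve(slope_a=150.0, source="measured")


def conductivity_slope_theoretical(viscosity_cP: float,
                                   mean_ionic_radius_A: float) -> float:
    """Theoretical calibration slope a = e² N_A / (6 π η a_h).

    This is the Nernst–Einstein / Stokes estimate of the molar conductivity of
    a 1:1 electrolyte whose two ions share a mean hydrodynamic radius ``a_h``.
    Returned in μS cm⁻¹ per mM.  Inversely proportional to both arguments.
    """
    if viscosity_cP <= 0:
        raise ValueError(f"viscosity_cP must be positive, got {viscosity_cP}")
    if mean_ionic_radius_A <= 0:
        raise ValueError(
            f"mean_ionic_radius_A must be positive, got {mean_ionic_radius_A}"
        )
    eta = viscosity_cP * CP_TO_PA_S
    a_h = mean_ionic_radius_A * ANGSTROM_TO_M
    # molar conductivity in S m^2 / mol
    lam = ELEMENTARY_CHARGE ** 2 * AVOGADRO / (6.0 * math.pi * eta * a_h)
    # s = lam * c ; with c in mM == mol/m^3, s is in S/m; 1 S/m == 1e4 μS/cm
    return lam * 1.0e4


def theoretical_calibration(viscosity_cP: float = 0.89,
                            mean_ionic_radius_A: float = 1.415) -> CalibrationCurve:
    """Calibration curve from the Stokes estimate; defaults use water viscosity
    and the mean of the Na⁺ (1.01 Å) and Cl⁻ (1.82 Å) radii."""
    return CalibrationCurve(
        slope_a=conductivity_slope_theoretical(viscosity_cP, mean_ionic_radius_A),
        reference_viscosity_cP=viscosity_cP,
        source="theoretical",
    )


def ionic_strength_from_conductivity(conductivity_uS_cm: float,
                                     calibration: CalibrationCurve,
                                     solvent_viscosity_cP: Optional[float] = None,
                                     ) -> float:
    """Infer ionic strength c₀ (mM) from measured conductivity s (μS cm⁻¹).

    c₀ = (s / a) × (η_solvent / η_ref).  The viscosity factor corrects the
    water-calibrated slope for a different solvent under the assumption that
    ionic mobility scales as 1/η at identical hydrodynamic radii, so the same
    salt concentration conducts less in a more viscous solvent.
    """
    if conductivity_uS_cm < 0:
        raise ValueError(
            f"conductivity_uS_cm must be non-negative, got {conductivity_uS_cm}"
        )
    eta = (calibration.reference_viscosity_cP if solvent_viscosity_cP is None
           else solvent_viscosity_cP)
    if eta <= 0:
        raise ValueError(f"solvent_viscosity_cP must be positive, got {eta}")
    return (conductivity_uS_cm / calibration.slope_a) * (
        eta / calibration.reference_viscosity_cP)


def osmolyte_viscosity_ratio(c_b_M: float, B_visc: float, D_visc: float) -> float:
    """Relative viscosity η/η₀ = 1 + B c_b + D c_b² of an osmolyte solution.

    ``c_b_M`` is the osmolyte molarity; B (M⁻¹) and D (M⁻²) are the empirical
    Jones–Dole-type coefficients of the solute.
    """
    if c_b_M < 0:
        raise ValueError(f"c_b_M must be non-negative, got {c_b_M}")
    return 1.0 + B_visc * c_b_M + D_visc * c_b_M ** 2


# ---------------------------------------------------------------------------
# Solvent registry
# ---------------------------------------------------------------------------

def load_solvent_registry(path: Optional[str] = None) -> dict[str, Medium]:
    """Load the solvent registry (name -> Medium).

    Without ``path`` the registry shipped with the package is used: nominal
    literature permittivities and viscosities at 298 K for the solvents
    studied with this pipeline.  Values are placeholders a user may override
    with a custom YAML file of the same shape.
    """
    if path is None:
        text = (resources.files("esolv") / "data" / "solvents.yaml").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    raw = yaml.safe_load(text)
    registry: dict[str, Medium] = {}
    for name, rec in raw.items():
        registry[name] = Medium(
            name=name,
            relative_permittivity=float(rec["relative_permittivity"]),
            viscosity_cP=float(rec["viscosity_cP"]),
            temperature_K=float(rec.get("temperature_K", 298.0)),
            notes=str(rec.get("notes", "")),
        )
    return registry
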