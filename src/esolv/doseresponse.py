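"""Osmolyte/surfactant dose–response analysis.

Additives in the medium weaken (or sustain) the electrosolvation attraction;
the experiment's summary statistic is the bulk concentration c½ at which the
normalized well depth w/w_max drops to one half.  The normalized depths are
fitted with a fixed-asymptote Hill curve on a log-concentration axis,

    f(c) = 1 / (1 + (c / c½)^h),

and surface enrichment follows the Boltzmann relation c_s = c_b e^{−u/k_BT},
where u is the adsorption PMF minimum of the additive at the particle
surface.  Under a constant-c_s threshold model ln c½ is linear in u with
unit slope (per k_BT), which the affinity regression quantifies.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence, Tuple

import numpy as np
from scipy.optimize import curve_fit
from scipy.stats import linregress

from .synthetic import DoseResponseSeries

__all__ = [
    "SigmoidFit", "AffinityRecord",
    "normalize_depths", "fit_sigmoid", "boltzmann_surface_concentration",
    "affinity_regression", "u_from_kJ_per_mol",
]


@dataclass
class SigmoidFit:
    """Fitted half-maximal concentration and Hill exponent."""

    c_half_M: float
    hill: float
    residual: float  # rms residual on the normalized scale
    n_points: int
    covariance: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.c_half_M <= 0 or self.hill <= 0:
            raise ValueError("c_half and hill must be positive")

    def predict(self, c_b_M: np.ndarray) -> np.ndarray:
        c = np.asarray(c_b_M, dtype=float)
        return 1.0 / (1.0 + (c / self.c_half_M) ** self.hill)


@dataclass(frozen=True)
class AffinityRecord:
    """One additive: its adsorption PMF minimum u (k_BT) and measured c½."""

    additive: str
    u_kBT: float
    c_half_M: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.u_kBT):
            raise ValueError("u must be finite")
        if self.c_half_M <= 0:
            raise ValueError("c_half must be positive")


def normalize_depths(series: DoseResponseSeries) -> np.ndarray:
    """Elementwise w/w_max: 1 at the reference attraction, 0 when it vanishes."""
    if series.w_max_kBT == 0:
        raise ValueError(
            "w_max is zero: no attraction in the reference medium to "
            "normalize against"
        )
    return series.w_kBT / series.w_max_kBT


def fit_sigmoid(series: DoseResponseSeries) -> SigmoidFit:
    """Least-squares Hill fit of w/w_max against log concentration.

    Asymptotes are fixed at 1 and 0 (matching the normalization), leaving
    (c½, h) free; by construction the fitted curve passes through 0.5 at
    c½.  Series lacking a decreasing trend are rejected as non-identifiable.
    """
    y = normalize_depths(series)
    c = series.c_b_M
    if np.any(c <= 0):
        raise ValueError("sigmoid fit needs strictly positive concentrations")
    if len(c) < 4:
        raise ValueError("need at least 4 points spanning both plateaus")
    if np.ptp(y) < 1e-12:
        raise ValueError("non-identifiable: all normalized depths are equal")
    # direction check: response must decrease with concentration overall
    if float(np.mean(y[: len(y) // 2])) <= float(np.mean(y[len(y) // 2:])):
        raise ValueError(
            "non-identifiable: normalized depths do not decrease with "
            "concentration"
        )

    logc = np.log(c)

    def model(lc, log_chalf, hill):
        return 1.0 / (1.0 + np.exp(hill * (lc - log_chalf)))

    # initial c_half: concentration where y crosses 0.5 (interpolated)
    try:
        lc0 = float(np.interp(0.5, y[::-1], logc[::-1]))
    except Exception:
        lc0 = float(np.median(logc))
    popt, pcov = curve_fit(model, logc, y, p0=[lc0, 1.0],
                           maxfev=10000)
    log_chalf, hill = popt
    if hill <= 0:
        raise ValueError("non-identifiable: fitted Hill exponent is not positive")
    resid = float(np.sqrt(np.mean((model(logc, *popt) - y) ** 2)))
    return SigmoidFit(c_half_M=float(np.exp(log_chalf)), hill=float(hill),
                      residual=resid, n_points=len(c), covariance=pcov)


def boltzmann_surface_concentration(c_b_M: float, u_kBT: float) -> float:
    """Surface concentration from the Boltzmann factor: c_s = c_b e^{−u}.

    ``u_kBT`` is the PMF minimum in k_BT units (negative for adsorbing
    species, so adsorption enriches the surface: c_s > c_b).
    """
    if c_b_M < 0:
        raise ValueError("c_b must be non-negative")
    return c_b_M * math.exp(-u_kBT)


def u_from_kJ_per_mol(u_kJ_mol: float, temperature_K: float = 298.0) -> float:
    """Convert a PMF depth from kJ/mol to k_BT units at the given temperature."""
    from .media import AVOGADRO, BOLTZMANN
    return u_kJ_mol * 1e3 / (AVOGADRO * BOLTZMANN * temperature_K)


def affinity_regression(records: Sequence[AffinityRecord],
                        ) -> Tuple[float, float, float]:
    """Ordinary least squares of ln c½ on u across additives.

    Returns (slope per k_BT, intercept, r²).  Under the constant-c_s model
    ln c½ = ln c_s + u, so the slope is 1 per k_BT and the intercept is the
    common log surface concentration at threshold.
    """
    records = list(records)
    if len(records) < 3:
        raise ValueError(f"need at least 3 records, got {len(records)}")
    u = np.array([r.u_kBT for r in records])
    y = np.log([r.c_half_M for r in records])
    if np.ptp(u) == 0:
        raise ValueError("degenerate abscissa: all u values identical")
    res = linregress(u, y)
    return float(res.slope), float(res.intercept), float(res.rvalue ** 2)
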