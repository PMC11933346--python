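"""2-D overdamped Brownian dynamics of polydisperse spheres in a periodic box.

The simulator mimics a gravity-sedimented colloidal monolayer: spheres move
in the plane only (the vertical degree of freedom is frozen, representing
sedimentation), interact through a supplied pair potential evaluated at the
*surface* separation x = r_ij − R_i − R_j — so the interaction law is shared
by every particle pair regardless of individual radii — and obey the
Euler–Maruyama overdamped update

    Δr = (D / k_B T) F Δt + sqrt(2 D Δt) ξ,     ξ ~ N(0, 1) per axis.

Positions are wrapped into [0, L) with minimum-image pair distances.  Units:
μm, seconds, k_BT.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np
from numba import njit

from .media import BOLTZMANN, CP_TO_PA_S, UM_TO_M
from .potentials import ElectrosolvationPotential

__all__ = [
    "SimulationConfig", "Ensemble", "RunLog",
    "initialize_random", "run", "potential_energy_per_particle",
    "stokes_einstein_diffusion", "default_timestep",
]


def stokes_einstein_diffusion(radius_um: float, viscosity_cP: float = 0.89,
                              temperature_K: float = 298.0) -> float:
    """Stokes–Einstein diffusion coefficient D = k_BT / (6πηR) in μm²/s."""
    if radius_um <= 0 or viscosity_cP <= 0:
        raise ValueError("radius and viscosity must be positive")
    D = (BOLTZMANN * temperature_K
         / (6.0 * math.pi * viscosity_cP * CP_TO_PA_S * radius_um * UM_TO_M))
    return D / UM_TO_M ** 2


@dataclass(frozen=True)
class SimulationConfig:
    """Run parameters for the 2-D BD simulator.

    ``timestep_s`` and ``interaction_cutoff_um`` may be left None and are
    then derived from the active potential at run start (see
    :func:`default_timestep`); ``diffusion_um2_s`` defaults to the
    Stokes–Einstein value for the mean radius in water.
    """

    box_length_um: float
    number_density_per_um2: float
    radius_mean_um: float = 2.41
    radius_sd_um: float = 0.0
    diffusion_um2_s: Optional[float] = None
    timestep_s: Optional[float] = None
    n_steps: int = 100_000
    sample_interval: int = 1000
    seed: int = 0
    interaction_cutoff_um: Optional[float] = None
    x_floor_um: float = 1.0e-3  # force capped below this surface separation

    def __post_init__(self) -> None:
        if self.box_length_um <= 0:
            raise ValueError(f"box_length_um must be positive, got {self.box_length_um}")
        if self.number_density_per_um2 <= 0:
            raise ValueError("number_density_per_um2 must be positive")
        if self.radius_mean_um <= 0 or self.radius_sd_um < 0:
            raise ValueError("radius_mean_um must be > 0 and radius_sd_um >= 0")
        if self.timestep_s is not None and self.timestep_s <= 0:
            raise ValueError("timestep_s must be positive")
        if self.n_steps < 1 or self.sample_interval < 1:
            raise ValueError("n_steps and sample_interval must be >= 1")
        if (self.interaction_cutoff_um is not None
                and self.interaction_cutoff_um >= self.box_length_um / 2):
            raise ValueError(
                "interaction_cutoff_um must be < box_length/2 for the "
                "minimum-image convention to be valid"
            )

    @property
    def n_particles(self) -> int:
        return int(round(self.number_density_per_um2 * self.box_length_um ** 2))

    def resolved_diffusion(self) -> float:
        if self.diffusion_um2_s is not None:
            return self.diffusion_um2_s
        return stokes_einstein_diffusion(self.radius_mean_um)


@dataclass
class Ensemble:
    """2-D particle positions and radii in a periodic square box (μm)."""

    positions: np.ndarray  # (N, 2)
    radii: np.ndarray  # (N,)
    box_length_um: float
    periodic: bool = True

    def __post_init__(self) -> None:
        self.positions = np.atleast_2d(np.asarray(self.positions, dtype=float))
        if self.positions.size == 0:
            self.positions = self.positions.reshape(0, 2)
        self.radii = np.asarray(self.radii, dtype=float).ravel()
        if self.positions.shape[0] != self.radii.shape[0]:
            raise ValueError("positions and radii must have equal length")
        if self.positions.size and self.positions.shape[1] != 2:
            raise ValueError("positions must be (N, 2)")
        if np.any(self.radii <= 0):
            raise ValueError("all radii must be positive")
        if self.positions.size and (
                np.any(self.positions < 0)
                or np.any(self.positions >= self.box_length_um)):
            raise ValueError("all coordinates must lie in [0, box_length)")

    def __len__(self) -> int:
        return self.positions.shape[0]


@dataclass
class RunLog:
    """Per-sample bookkeeping of a BD run."""

    step_indices: np.ndarray
    potential_energy_per_particle: np.ndarray  # k_BT
    stationary: bool
    stationary_from: int  # index into samples where the stationary tail begins
    timestep_s: float
    notes: str = ""


# ---------------------------------------------------------------------------
# Initialization
# ---------------------------------------------------------------------------

def initialize_random(config: SimulationConfig) -> Ensemble:
    """Random (overlap-relaxed) particle placement with truncated-normal radii.

    Radii are drawn from N(mean, sd) clipped to ±3 sd and to positive values.
    After uniform placement, particles overlapping a neighbour are resampled
    for a bounded number of sweeps — at the dilute densities of interest this
    converges in a couple of sweeps; area fractions above 0.7 are refused.
    """
    N = config.n_particles
    if N < 2:
        raise ValueError(
            f"need at least 2 particles; density {config.number_density_per_um2} "
            f"in a {config.box_length_um} um box gives N={N}"
        )
    rng = np.random.default_rng(config.seed)
    if config.radius_sd_um > 0:
        radii = rng.normal(config.radius_mean_um, config.radius_sd_um, size=N)
        lo = max(config.radius_mean_um - 3 * config.radius_sd_um,
                 np.finfo(float).tiny)
        hi = config.radius_mean_um + 3 * config.radius_sd_um
        radii = np.clip(radii, lo, hi)
    else:
        radii = np.full(N, config.radius_mean_um)

    area_fraction = float(np.sum(math.pi * radii ** 2)) / config.box_length_um ** 2
    if area_fraction > 0.7:
        raise ValueError(
            f"infeasible packing: area fraction {area_fraction:.2f} > 0.7"
        )

    L = config.box_length_um
    pos = rng.uniform(0.0, L, size=(N, 2))
    for _ in range(200):
        bad = _overlapping(pos, radii, L)
        if not bad.size:
            break
        pos[bad] = rng.uniform(0.0, L, size=(bad.size, 2))
    return Ensemble(positions=pos, radii=radii, box_length_um=L)


def _overlapping(pos: np.ndarray, radii: np.ndarray, L: float) -> np.ndarray:
    """Indices of particles whose surface separation to some other is < 0."""
    d = pos[:, None, :] - pos[None, :, :]
    d -= L * np.round(d / L)
    r = np.sqrt((d ** 2).sum(-1))
    np.fill_diagonal(r, np.inf)
    x = r - radii[:, None] - radii[None, :]
    return np.unique(np.nonzero(x < 0.0)[0])


# ---------------------------------------------------------------------------
# Integration kernel
# ---------------------------------------------------------------------------

@njit(cache=True, inline="always")
def _pair_force(dx, dy, ri, rj, A, B, k1, k2, cutoff_x, x_floor):
    r = math.sqrt(dx * dx + dy * dy)
    x = r - ri - rj
    if x > cutoff_x or r <= 0.0:
        return 0.0
    xs = x if x > x_floor else x_floor
    # f = -dU/dx, positive pushes surfaces apart (along +r_ij)
    return (A * k1 * math.exp(-k1 * xs) + B * k2 * math.exp(-k2 * xs)) / r


@njit(cache=True)
def _bd_kernel(pos, radii, L, A, B, k1, k2, cutoff_x, x_floor,
               D, dt, n_steps, sample_interval, seed,
               frames, energies, disp):  # pragma: no cover - jitted
    np.random.seed(seed)
    N = pos.shape[0]
    mob = D * dt  # (D / kBT) * dt with forces in kBT/um
    sig = math.sqrt(2.0 * D * dt)
    fx = np.empty(N)
    fy = np.empty(N)
    interacting = A != 0.0 or B != 0.0

    # linked-cell neighbour search: cell edge >= interaction range in centre
    # distance; direct O(N^2) loop when the box holds too few cells
    rmax = 0.0
    for i in range(N):
        if radii[i] > rmax:
            rmax = radii[i]
    r_int = cutoff_x + 2.0 * rmax
    ncell = int(L / r_int) if r_int > 0.0 else 0
    use_cells = interacting and ncell >= 4
    if not use_cells:
        ncell = 1
    cell_len = L / ncell
    head = np.empty(ncell * ncell, dtype=np.int64)
    nxt = np.empty(N, dtype=np.int64)

    n_sample = 0
    for step in range(n_steps):
        for i in range(N):
            fx[i] = 0.0
            fy[i] = 0.0
        if interacting:
            if use_cells:
                for c in range(ncell * ncell):
                    head[c] = -1
                for i in range(N):
                    cx = int(pos[i, 0] / cell_len)
                    cy = int(pos[i, 1] / cell_len)
                    if cx >= ncell:
                        cx = ncell - 1
                    if cy >= ncell:
                        cy = ncell - 1
                    c = cy * ncell + cx
                    nxt[i] = head[c]
                    head[c] = i
                for cy in range(ncell):
                    for cx in range(ncell):
                        c = cy * ncell + cx
                        # half neighbour stencil (self + 4) counts pairs once
                        for s in range(5):
                            if s == 0:
                                ox, oy = 0, 0
                            elif s == 1:
                                ox, oy = 1, 0
                            elif s == 2:
                                ox, oy = 1, 1
                            elif s == 3:
                                ox, oy = 0, 1
                            else:
                                ox, oy = -1, 1
                            nx_ = (cx + ox) % ncell
                            ny_ = (cy + oy) % ncell
                            c2 = ny_ * ncell + nx_
                            i = head[c]
                            while i >= 0:
                                j = head[c2] if c2 != c else nxt[i]
                                while j >= 0:
                                    dx = pos[i, 0] - pos[j, 0]
                                    dy = pos[i, 1] - pos[j, 1]
                                    dx -= L * round(dx / L)
                                    dy -= L * round(dy / L)
                                    fr = _pair_force(dx, dy, radii[i],
                                                     radii[j], A, B, k1, k2,
                                                     cutoff_x, x_floor)
                                    if fr != 0.0:
                                        fx[i] += fr * dx
                                        fy[i] += fr * dy
                                        fx[j] -= fr * dx
                                        fy[j] -= fr * dy
                                    j = nxt[j]
                                i = nxt[i]
            else:
                for i in range(N):
                    for j in range(i + 1, N):
                        dx = pos[i, 0] - pos[j, 0]
                        dy = pos[i, 1] - pos[j, 1]
                        dx -= L * round(dx / L)
                        dy -= L * round(dy / L)
                        fr = _pair_force(dx, dy, radii[i], radii[j],
                                         A, B, k1, k2, cutoff_x, x_floor)
                        if fr != 0.0:
                            fx[i] += fr * dx
                            fy[i] += fr * dy
                            fx[j] -= fr * dx
                            fy[j] -= fr * dy
        xi = np.random.standard_normal(2 * N)
        for i in range(N):
            ddx = mob * fx[i] + sig * xi[2 * i]
            ddy = mob * fy[i] + sig * xi[2 * i + 1]
            if not (math.isfinite(ddx) and math.isfinite(ddy)):
                return -(step + 1)  # NaN/Inf failure, report step
            disp[i, 0] += ddx
            disp[i, 1] += ddy
            nx = pos[i, 0] + ddx
            ny = pos[i, 1] + ddy
            nx -= L * math.floor(nx / L)
            ny -= L * math.floor(ny / L)
            pos[i, 0] = nx
            pos[i, 1] = ny
        if (step + 1) % sample_interval == 0:
            for i in range(N):
                frames[n_sample, i, 0] = pos[i, 0]
                frames[n_sample, i, 1] = pos[i, 1]
            # potential energy per particle (infrequent: direct pair sum)
            e = 0.0
            if interacting:
                for i in range(N):
                    for j in range(i + 1, N):
                        dx = pos[i, 0] - pos[j, 0]
                        dy = pos[i, 1] - pos[j, 1]
                        dx -= L * round(dx / L)
                        dy -= L * round(dy / L)
                        r = math.sqrt(dx * dx + dy * dy)
                        x = r - radii[i] - radii[j]
                        if x > cutoff_x:
                            continue
                        xs = x if x > x_floor else x_floor
                        e += A * math.exp(-k1 * xs) + B * math.exp(-k2 * xs)
            energies[n_sample] = e / N
            n_sample += 1
    return n_sample


def default_timestep(config: SimulationConfig,
                     potential: ElectrosolvationPotential) -> float:
    """Timestep such that the rms Brownian step sqrt(2 D dt) resolves the
    attractive well: ≤ min(0.1 κ₂⁻¹, 10 nm) for a non-null potential."""
    D = config.resolved_diffusion()
    if potential.is_null:
        step = 0.01  # 10 nm; free diffusion has no length scale to resolve
    else:
        step = min(0.1 / potential.kappa2, 0.01)
    return step ** 2 / (2.0 * D)


def _resolve_run_parameters(config: SimulationConfig,
                            potential: ElectrosolvationPotential
                            ) -> Tuple[float, float]:
    dt = config.timestep_s
    if dt is None:
        dt = default_timestep(config, potential)
    D = config.resolved_diffusion()
    if not potential.is_null:
        rms = math.sqrt(2.0 * D * dt)
        if rms >= 0.1 / potential.kappa2:
            raise ValueError(
                f"rms Brownian step {rms:.3g} um must stay below 0.1/kappa2 = "
                f"{0.1 / potential.kappa2:.3g} um; reduce timestep_s"
            )
    cutoff = config.interaction_cutoff_um
    if cutoff is None:
        cutoff = potential.cutoff(1e-3) if not potential.is_null else 0.0
        max_geom = (config.box_length_um / 2
                    - 2 * (config.radius_mean_um + 3 * config.radius_sd_um))
        cutoff = min(cutoff, max(max_geom, 0.0))
    return dt, cutoff


def run(config: SimulationConfig, ensemble: Ensemble,
        potential: ElectrosolvationPotential,
        ) -> Tuple[List[Ensemble], RunLog]:
    """Integrate the ensemble for ``config.n_steps`` steps.

    Returns the frames sampled every ``sample_interval`` steps and a
    :class:`RunLog` with the per-particle potential-energy series and a
    stationarity assessment of its trailing window.  Identical
    (config, ensemble, potential) triples give bit-identical output.
    """
    frames_arr, energies, steps, dt = run_arrays(config, ensemble, potential)
    frames = [Ensemble(positions=frames_arr[k].copy(), radii=ensemble.radii.copy(),
                       box_length_um=config.box_length_um)
              for k in range(frames_arr.shape[0])]
    stat, start = stationarity(energies)
    log = RunLog(step_indices=steps, potential_energy_per_particle=energies,
                 stationary=stat, stationary_from=start, timestep_s=dt)
    return frames, log


def run_arrays(config: SimulationConfig, ensemble: Ensemble,
               potential: ElectrosolvationPotential,
               ) -> Tuple[np.ndarray, np.ndarray, np.ndarray, float]:
    """Array-level BD run: (frames (S,N,2), energy/particle (S,), step indices,
    timestep).  The ensemble is not modified."""
    dt, cutoff = _resolve_run_parameters(config, potential)
    n_samples = config.n_steps // config.sample_interval
    N = len(ensemble)
    frames = np.empty((n_samples, N, 2))
    energies = np.empty(n_samples)
    disp = np.zeros((N, 2))
    pos = ensemble.positions.copy()
    rc = _bd_kernel(pos, ensemble.radii, config.box_length_um,
                    potential.A, potential.B, potential.kappa1, potential.kappa2,
                    cutoff, config.x_floor_um,
                    config.resolved_diffusion(), dt,
                    config.n_steps, config.sample_interval,
                    config.seed % 2 ** 31,
                    frames, energies, disp)
    if rc < 0:
        raise FloatingPointError(
            f"non-finite displacement at step {-rc - 1}; "
            "reduce the timestep or check the potential amplitudes"
        )
    steps = (np.arange(n_samples) + 1) * config.sample_interval
    return frames, energies, steps, dt


# ---------------------------------------------------------------------------
# Observables
# ---------------------------------------------------------------------------

def potential_energy_per_particle(ensemble: Ensemble,
                                  potential: ElectrosolvationPotential,
                                  cutoff_um: Optional[float] = None) -> float:
    """(1/N) Σ_{i<j} U(x_ij) over pairs within the cutoff (k_BT)."""
    N = len(ensemble)
    if N == 0 or potential.is_null:
        return 0.0
    if cutoff_um is None:
        cutoff_um = potential.cutoff(1e-3)
    L = ensemble.box_length_um
    d = ensemble.positions[:, None, :] - ensemble.positions[None, :, :]
    d -= L * np.round(d / L)
    r = np.sqrt((d ** 2).sum(-1))
    x = r - ensemble.radii[:, None] - ensemble.radii[None, :]
    iu = np.triu_indices(N, k=1)
    xs = x[iu]
    sel = xs <= cutoff_um
    xs = np.maximum(xs[sel], 1.0e-3)
    return float(np.sum(potential.evaluate(xs))) / N


def pairwise_forces(ensemble: Ensemble, potential: ElectrosolvationPotential,
                    cutoff_um: Optional[float] = None) -> np.ndarray:
    """(N, 2) deterministic pair forces (k_BT/μm) on each particle, with the
    same minimum-image, cutoff and contact-cap conventions as the
    integrator.  Being strictly pairwise-additive, they sum to zero."""
    N = len(ensemble)
    out = np.zeros((N, 2))
    if N == 0 or potential.is_null:
        return out
    if cutoff_um is None:
        cutoff_um = potential.cutoff(1e-3)
    L = ensemble.box_length_um
    d = ensemble.positions[:, None, :] - ensemble.positions[None, :, :]
    d -= L * np.round(d / L)
    r = np.sqrt((d ** 2).sum(-1))
    np.fill_diagonal(r, np.inf)
    x = r - ensemble.radii[:, None] - ensemble.radii[None, :]
    xs = np.maximum(x, 1.0e-3)
    f = potential.force(np.where(np.isfinite(xs), xs, 1.0))
    f = np.where((x <= cutoff_um) & np.isfinite(r), f, 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        fr = np.where(r > 0, f / r, 0.0)
    out[:, 0] = (fr * d[:, :, 0]).sum(axis=1)
    out[:, 1] = (fr * d[:, :, 1]).sum(axis=1)
    return out


def stationarity(energies: np.ndarray, window_frac: float = 0.2,
                 n_boot: int = 200, seed: int = 12345,
                 ) -> Tuple[bool, int]:
    """Assess stationarity of the energy series over its trailing window.

    Fits a linear trend to the last ``window_frac`` of samples and bootstraps
    the slope (resampling points with replacement); the series is declared
    stationary when the 95% bootstrap interval of the slope contains zero,
    or when the window is degenerate (constant / too short).

    Returns (stationary, start-index of the trailing window).
    """
    n = len(energies)
    start = max(0, int(math.floor(n * (1.0 - window_frac))))
    window = np.asarray(energies[start:], dtype=float)
    m = len(window)
    if m < 4 or np.ptp(window) == 0.0:
        return True, start
    t = np.arange(m, dtype=float)
    rng = np.random.default_rng(seed)
    slopes = np.empty(n_boot)
    for b in range(n_boot):
        idx = rng.integers(0, m, size=m)
        ti, wi = t[idx], window[idx]
        if np.ptp(ti) == 0.0:
            slopes[b] = 0.0
        else:
            slopes[b] = np.polyfit(ti, wi, 1)[0]
    lo, hi = np.percentile(slopes, [2.5, 97.5])
    return bool(lo <= 0.0 <= hi), start


def unwrapped_msd(config: SimulationConfig, ensemble: Ensemble,
                  potential: ElectrosolvationPotential) -> Tuple[float, float]:
    """Run the simulation and return (mean-squared displacement in μm²,
    elapsed time in s) from the cumulative unwrapped displacements —
    a free-diffusion diagnostic (MSD = 4 D t in 2-D for a null potential)."""
    dt, cutoff = _resolve_run_parameters(config, potential)
    N = len(ensemble)
    n_samples = config.n_steps // config.sample_interval
    frames = np.empty((n_samples, N, 2))
    energies = np.empty(n_samples)
    disp = np.zeros((N, 2))
    pos = ensemble.positions.copy()
    _bd_kernel(pos, ensemble.radii, config.box_length_um,
               potential.A, potential.B, potential.kappa1, potential.kappa2,
               cutoff, config.x_floor_um, config.resolved_diffusion(), dt,
               config.n_steps, config.sample_interval, config.seed % 2 ** 31,
               frames, energies, disp)
    msd = float(np.mean((disp ** 2).sum(axis=1)))
    return msd, config.n_steps * dt
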