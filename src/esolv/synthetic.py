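"""Synthetic-data generators with known ground truth.

Every generator returns ``(data, truth)`` where ``truth`` is a JSON-able
dict recording the generating parameters — the ground-truth "sidecar" that
recovery tests read instead of re-deriving anything from pipeline output.
All randomness flows from a single master seed through named substreams, so
a given (generator, seed) pair is fully reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
from scipy.optimize import brentq

from .bdsim import Ensemble, SimulationConfig, initialize_random, run
from .interfacial import MolecularFrame
from .potentials import ElectrosolvationPotential

__all__ = [
    "ProfileSpec", "DoseSpec", "DoseResponseSeries",
    "gen_ideal_gas", "gen_hcp_cluster", "gen_equilibrium_ensemble",
    "gen_capacitor_frames", "gen_hbond_config", "gen_dose_series",
]

_STREAMS = {"ideal_gas": 11, "hcp": 13, "ensemble": 17, "capacitor": 19,
            "hbond": 23, "dose": 29}


def _rng(master_seed: int, stream: str, k: int = 0) -> np.random.Generator:
    return np.random.default_rng([master_seed % 2 ** 31, _STREAMS[stream], k])


# ---------------------------------------------------------------------------
# Particle ensembles
# ---------------------------------------------------------------------------

def gen_ideal_gas(n: int, box_length_um: float, seed: int = 0,
                  radius_um: float = 1.0) -> Tuple[Ensemble, dict]:
    """Uniform random points in the periodic box: g(r) ≈ 1 everywhere."""
    rng = _rng(seed, "ideal_gas")
    pos = rng.uniform(0.0, box_length_um, size=(n, 2))
    ens = Ensemble(positions=pos, radii=np.full(n, radius_um),
                   box_length_um=box_length_um)
    return ens, {"generator": "ideal_gas", "n": n, "box_length_um": box_length_um,
                 "radius_um": radius_um, "seed": seed}


def gen_hcp_cluster(n_shells: int, x_min_um: float, radius_um: float,
                    box_length_um: float, seed: int = 0,
                    ) -> Tuple[Ensemble, dict]:
    """Centred hexagonal (2-D hcp) cluster with lattice constant 2R + x_min.

    ``n_shells`` = 0 gives a single particle; shell k adds 6k particles
    (1, 7, 19, 37, ... particles in total).  Interior particles have
    coordination number 6; nearest-neighbour centre distance is exactly
    2R + x_min.
    """
    s = 2.0 * radius_um + x_min_um
    pts = [(0.0, 0.0)]
    # axial coordinates of a triangular lattice within n_shells rings
    for q in range(-n_shells, n_shells + 1):
        for r in range(-n_shells, n_shells + 1):
            if q == 0 and r == 0:
                continue
            if max(abs(q), abs(r), abs(-q - r)) <= n_shells:
                x = s * (q + r / 2.0)
                y = s * (math.sqrt(3.0) / 2.0) * r
                pts.append((x, y))
    arr = np.asarray(pts) + box_length_um / 2.0
    extent = 2 * n_shells * s + 2 * radius_um
    if extent > box_length_um:
        raise ValueError(
            f"cluster extent {extent:.2f} um exceeds box {box_length_um} um"
        )
    ens = Ensemble(positions=arr, radii=np.full(len(arr), radius_um),
                   box_length_um=box_length_um)
    truth = {"generator": "hcp_cluster", "n_shells": n_shells,
             "spacing_um": s, "x_min_um": x_min_um, "radius_um": radius_um,
             "n_particles": len(arr), "seed": seed}
    assert len(arr) == 1 + 3 * n_shells * (n_shells + 1)
    return ens, truth


def gen_equilibrium_ensemble(potential: ElectrosolvationPotential,
                             config: SimulationConfig,
                             ) -> Tuple[List[Ensemble], dict]:
    """Equilibrium frames from a BD run under the given potential.

    Runs ``config.n_steps`` from random placement and returns the frames in
    the stationary tail of the potential-energy series (at least the final
    half of samples — the same tail convention the inference evaluations
    use, so recovery experiments compare like with like), with the
    generating parameters in the sidecar.
    """
    ens = initialize_random(config)
    frames, log = run(config, ens, potential)
    start = min(log.stationary_from, max(0, len(frames) - max(1, len(frames) // 2)))
    tail = frames[start:]
    truth = {"generator": "equilibrium_ensemble",
             "A_kBT": potential.A, "B_kBT": potential.B,
             "kappa1_per_um": potential.kappa1, "kappa2_per_um": potential.kappa2,
             "box_length_um": config.box_length_um,
             "number_density_per_um2": config.number_density_per_um2,
             "radius_mean_um": config.radius_mean_um,
             "seed": config.seed, "stationary": log.stationary,
             "n_frames": len(tail)}
    return tail, truth


def gen_separated(n: int, box_length_um: float, radius_um: float,
                  min_gap_um: float = 1.0, seed: int = 0,
                  max_tries: int = 100_000) -> Tuple[Ensemble, dict]:
    """``n`` discs with surface gaps ≥ ``min_gap_um``, fully inside the box
    (margin of one radius from every border) — the input class for
    localization round-trip tests, where discs must neither merge nor be
    clipped by the field of view.
    """
    rng = _rng(seed, "ideal_gas", 1)
    lo, hi = radius_um, box_length_um - radius_um
    if hi <= lo:
        raise ValueError("box too small for the disc radius")
    pts: List[np.ndarray] = []
    d_min = 2 * radius_um + min_gap_um
    tries = 0
    while len(pts) < n:
        cand = rng.uniform(lo, hi, size=2)
        if all(np.hypot(*(cand - p)) >= d_min for p in pts):
            pts.append(cand)
        tries += 1
        if tries > max_tries:
            raise RuntimeError(
                f"could not place {n} separated discs in {box_length_um} um"
            )
    ens = Ensemble(positions=np.array(pts).reshape(-1, 2),
                   radii=np.full(n, radius_um), box_length_um=box_length_um)
    truth = {"generator": "separated", "n": n, "radius_um": radius_um,
             "min_gap_um": min_gap_um, "box_length_um": box_length_um,
             "seed": seed}
    return ens, truth


# ---------------------------------------------------------------------------
# Capacitor (slab) molecular frames
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ProfileSpec:
    """Prescription for slab frames with a known interfacial dipole excess.

    The excess dipole density profile on each side integrates to
    ``excess_mu_D_nm2`` per species-weighted mixture (the generator's
    defining contract); the bulk is orientationally isotropic.
    ``species_mix`` maps species name -> (number fraction, per-species
    excess in D nm⁻²); fractions must sum to 1.
    """

    bulk_density_per_nm3: float = 33.0
    excess_mu_D_nm2: float = 0.85
    excess_mu_upper_D_nm2: Optional[float] = None  # defaults to the lower value
    excess_shape: str = "exponential"  # or "damped-oscillation"
    decay_length_nm: float = 0.3
    oscillation_period_nm: float = 0.25
    noise_sd_D: float = 0.0
    n_frames: int = 8
    box_nm: Tuple[float, float, float] = (4.0, 4.0, 6.0)
    species_mix: Optional[Dict[str, Tuple[float, float]]] = None
    dipole_magnitude_D: float = 2.35
    orientation_mode: str = "exact"  # or "vmf"

    @property
    def excess_per_side(self) -> Tuple[float, float]:
        hi = (self.excess_mu_D_nm2 if self.excess_mu_upper_D_nm2 is None
              else self.excess_mu_upper_D_nm2)
        return (self.excess_mu_D_nm2, hi)

    def resolved_mix(self) -> Dict[str, Tuple[float, float]]:
        if self.species_mix is None:
            return {"water": (1.0, self.excess_mu_D_nm2)}
        total = sum(f for f, _ in self.species_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"species fractions must sum to 1, got {total}")
        return dict(self.species_mix)

    @property
    def interface_thickness_nm(self) -> float:
        """Ground-truth interfacial thickness l: where the excess envelope
        has decayed to 5%."""
        return self.decay_length_nm * math.log(20.0)


def _excess_shape_fn(spec: ProfileSpec) -> Tuple[np.ndarray, np.ndarray]:
    """Normalized excess shape φ(z) on a fine grid over [0, l_true] with
    ∫ φ dz = 1 (truncated support)."""
    l = spec.interface_thickness_nm
    z = np.linspace(0.0, l, 2001)
    if spec.excess_shape == "exponential":
        raw = np.exp(-z / spec.decay_length_nm)
    elif spec.excess_shape == "damped-oscillation":
        raw = np.exp(-z / spec.decay_length_nm) * np.sin(
            2.0 * math.pi * z / spec.oscillation_period_nm - 0.25)
    else:
        raise ValueError(f"unknown excess_shape {spec.excess_shape!r}")
    norm = np.trapezoid(raw, z)
    if abs(norm) < 1e-12:
        raise ValueError("degenerate excess shape integrates to ~0")
    return z, raw / norm


def _vmf_kappa(mean_cos: float) -> float:
    """Concentration of the von Mises–Fisher distribution on the sphere whose
    mean resultant ⟨cosθ⟩ = coth(κ) − 1/κ equals ``mean_cos``."""
    if abs(mean_cos) < 1e-12:
        return 0.0
    sgn = math.copysign(1.0, mean_cos)
    m = abs(mean_cos)
    if m >= 1.0:
        raise ValueError("mean cosine must have magnitude < 1")

    def f(k):
        return 1.0 / math.tanh(k) - 1.0 / k - m

    return sgn * brentq(f, 1e-8, 1e4)


def _sample_vmf_cos(rng: np.random.Generator, kappa: float, n: int) -> np.ndarray:
    if kappa == 0.0:
        return rng.uniform(-1.0, 1.0, size=n)
    u = rng.uniform(0.0, 1.0, size=n)
    k = abs(kappa)
    c = 1.0 + np.log(u + (1.0 - u) * math.exp(-2.0 * k)) / k
    return c if kappa > 0 else -c


def gen_capacitor_frames(spec: ProfileSpec, seed: int = 0,
                         ) -> Tuple[List[MolecularFrame], dict]:
    """Slab frames with a prescribed excess dipole profile at both walls.

    Molecules are placed uniformly at the bulk density; those within the
    interfacial thickness l of a wall carry a mean inward-normal dipole
    component matched to the prescribed excess shape, everything else is
    isotropic.  In "exact" orientation mode the realized per-side,
    per-species dipole sum is rescaled to meet the analytic excess
    *exactly*; "vmf" mode draws orientations from a von Mises–Fisher
    distribution with the matching mean resultant (noisy path).  The
    contract — the realized excess integral equals the prescription — is
    asserted before frames are returned.
    """
    mix = spec.resolved_mix()
    bx, by, bz = spec.box_nm
    area = bx * by
    l_true = spec.interface_thickness_nm
    if 2 * l_true >= 0.8 * bz:
        raise ValueError("slab too thin for the requested interface thickness")
    zgrid, phi = _excess_shape_fn(spec)
    mu0 = spec.dipole_magnitude_D
    n_total = int(round(spec.bulk_density_per_nm3 * area * bz))

    species_names = list(mix)
    fracs = np.array([mix[s][0] for s in species_names])
    excesses = {s: mix[s][1] for s in species_names}

    frames: List[MolecularFrame] = []
    for k in range(spec.n_frames):
        rng = _rng(seed, "capacitor", k)
        pos = np.column_stack([rng.uniform(0, bx, n_total),
                               rng.uniform(0, by, n_total),
                               rng.uniform(0, bz, n_total)])
        sp_idx = rng.choice(len(species_names), size=n_total, p=fracs)
        species = np.array([species_names[i] for i in sp_idx], dtype=object)
        mu = np.zeros((n_total, 3))

        z = pos[:, 2]
        d_lo = z  # distance from lower wall (wall at 0)
        d_hi = bz - z
        side = np.where(d_lo <= d_hi, 0, 1)  # nearest wall
        d = np.minimum(d_lo, d_hi)
        interfacial = d < l_true
        exact = spec.orientation_mode == "exact"
        if not exact and spec.orientation_mode != "vmf":
            raise ValueError(
                f"unknown orientation_mode {spec.orientation_mode!r}")

        # bulk: isotropic orientations.  In "exact" mode bulk molecules are
        # laid out as z-matched antithetic pairs within each species (same z,
        # independent x/y, opposite cos theta), so every z-window integral of
        # the bulk dipole density vanishes identically while each molecule's
        # orientation stays isotropically distributed; "vmf" mode is fully
        # random.
        cos = rng.uniform(-1.0, 1.0, size=n_total)
        if exact:
            for si in range(len(species_names)):
                idx = np.nonzero((sp_idx == si) & ~interfacial)[0]
                n_pairs = len(idx) // 2
                a, b = idx[:n_pairs], idx[n_pairs:2 * n_pairs]
                pos[b, 2] = pos[a, 2]
                cos[b] = -cos[a]
                if len(idx) % 2:
                    cos[idx[-1]] = 0.0
        azim = rng.uniform(0.0, 2 * math.pi, size=n_total)
        sin = np.sqrt(np.maximum(0.0, 1.0 - cos ** 2))
        mu[:, 0] = mu0 * sin * np.cos(azim)
        mu[:, 1] = mu0 * sin * np.sin(azim)
        mu[:, 2] = mu0 * cos

        e_lo_total, e_hi_total = spec.excess_per_side
        side_scale = (1.0, (e_hi_total / e_lo_total) if e_lo_total != 0.0
                      else (1.0 if e_hi_total == e_lo_total else float("nan")))
        if math.isnan(side_scale[1]):
            raise ValueError(
                "per-side excess override requires a nonzero lower-side excess"
            )
        for si, sname in enumerate(species_names):
            f_s, ex_s = fracs[si], excesses[sname]
            rho_s = f_s * spec.bulk_density_per_nm3
            if rho_s <= 0:
                continue
            sel = (sp_idx == si) & interfacial
            if not np.any(sel):
                continue
            scale_sel = np.where(side[sel] == 0, side_scale[0], side_scale[1])
            target = ex_s * scale_sel * np.interp(d[sel], zgrid, phi) / rho_s
            if np.max(np.abs(target)) > mu0:
                raise ValueError(
                    f"excess {ex_s} D/nm^2 for {sname!r} needs a mean dipole "
                    f"beyond the molecular magnitude {mu0} D"
                )
            if exact:
                muz = target.copy()
                if spec.noise_sd_D > 0:
                    muz = muz + rng.normal(0.0, spec.noise_sd_D, size=len(muz))
                    muz = np.clip(muz, -mu0, mu0)
                # rescale so each side's realized sum meets the analytic excess
                for wall in (0, 1):
                    ws = side[sel] == wall
                    if not np.any(ws):
                        continue
                    want = ex_s * side_scale[wall]
                    realized = muz[ws].sum() / area
                    if abs(realized) > 1e-15:
                        muz[ws] *= (want / realized) if want != 0 else 0.0
                    elif want != 0:
                        raise RuntimeError("cannot rescale a zero-sum layer")
            else:
                muz = np.empty(len(target))
                for i, t in enumerate(target):
                    kap = _vmf_kappa(t / mu0)
                    muz[i] = mu0 * _sample_vmf_cos(rng, kap, 1)[0]
            # inward normal: +z at lower wall, -z at upper wall
            muz_lab = np.where(side[sel] == 0, muz, -muz)
            trans = np.sqrt(np.maximum(0.0, mu0 ** 2 - muz ** 2))
            az = rng.uniform(0.0, 2 * math.pi, size=len(muz))
            idx = np.nonzero(sel)[0]
            mu[idx, 0] = trans * np.cos(az)
            mu[idx, 1] = trans * np.sin(az)
            mu[idx, 2] = muz_lab

        if exact and spec.noise_sd_D == 0.0:
            # generator contract: realized excess equals prescription per side
            for wall, dist in ((0, d_lo), (1, d_hi)):
                nz = mu[:, 2] * (1.0 if wall == 0 else -1.0)
                got = nz[(dist < l_true)].sum() / area
                want = sum(excesses[s] for s in species_names) * side_scale[wall]
                assert abs(got - want) < 1e-8 * max(1.0, abs(want)), \
                    "generated excess does not meet the prescription"

        frames.append(MolecularFrame(
            species=species, positions_nm=pos, dipoles_D=mu,
            box_nm=spec.box_nm, normal_axis="z",
            wall_positions_nm=(0.0, bz)))

    truth = {"generator": "capacitor_frames", "seed": seed,
             "excess_mu_D_nm2": spec.excess_mu_D_nm2,
             "excess_per_side": list(spec.excess_per_side),
             "species_excess": {s: excesses[s] for s in species_names},
             "species_fraction": {s: float(f) for s, f in
                                  zip(species_names, fracs)},
             "bulk_density_per_nm3": spec.bulk_density_per_nm3,
             "z_int_nm": 0.0, "l_nm": l_true,
             "excess_shape": spec.excess_shape,
             "orientation_mode": spec.orientation_mode,
             "n_frames": spec.n_frames, "box_nm": list(spec.box_nm)}
    return frames, truth


# ---------------------------------------------------------------------------
# Hydrogen-bond configurations
# ---------------------------------------------------------------------------

def gen_hbond_config(n_bonds: int, n_decoys: int, box_nm: float = 10.0,
                     seed: int = 0) -> Tuple[MolecularFrame, dict]:
    """A frame with exactly ``n_bonds`` donor–H–acceptor pairs satisfying the
    geometric criterion and ``n_decoys`` pairs violating exactly one of the
    two criteria (alternating distance / angle violations).

    Pairs are placed on a coarse grid with ≥ 1 nm clearance so no accidental
    cross-pair bonds arise; the internal contract (planted count = criterion
    count by direct construction) is asserted before returning.
    """
    n_groups = n_bonds + n_decoys
    cell = 2.0
    per_side = int(math.ceil(n_groups ** (1.0 / 3.0)))
    if per_side * cell > box_nm:
        raise ValueError("box too small for the requested number of groups")
    rng = _rng(seed, "hbond")

    d_oh = 0.1  # donor-H covalent distance
    positions, species = [], []
    donors, hydros, acceptors = [], [], []

    def add_molecule(p, donor=None, hydrogen=None, acceptor=None):
        positions.append(p)
        species.append("water")
        donors.append(donor if donor is not None else [np.nan] * 3)
        hydros.append(hydrogen if hydrogen is not None else [np.nan] * 3)
        acceptors.append(acceptor if acceptor is not None else [np.nan] * 3)

    g = 0
    for gx in range(per_side):
        for gy in range(per_side):
            for gz in range(per_side):
                if g >= n_groups:
                    break
                base = np.array([gx, gy, gz]) * cell + 0.5
                u = rng.standard_normal(3)
                u /= np.linalg.norm(u)
                if g < n_bonds:
                    dist, ang = 0.28, 170.0
                else:
                    # decoys alternate: distance violated / angle violated
                    if (g - n_bonds) % 2 == 0:
                        dist, ang = 0.305, 180.0
                    else:
                        dist, ang = 0.28, 140.0
                dpos = base
                hpos = base + d_oh * u
                # acceptor at distance `dist` from donor, with D-H...A angle `ang`
                theta = math.radians(180.0 - ang)  # deviation from linear
                # build acceptor in the plane spanned by u and a perpendicular
                perp = np.cross(u, [0.0, 0.0, 1.0])
                if np.linalg.norm(perp) < 1e-8:
                    perp = np.cross(u, [0.0, 1.0, 0.0])
                perp /= np.linalg.norm(perp)
                # place A such that angle at H between D and A is `ang`
                # H->D = -u*d_oh ; choose H->A direction at angle `ang` from H->D
                dir_ha = -u * math.cos(math.radians(ang)) + perp * math.sin(
                    math.radians(ang))
                # solve |D-A| = dist with A = H + t*dir_ha
                # D - A = (D - H) - t dir  = u*(-d_oh)... use quadratic
                dh = dpos - hpos
                b = 2.0 * float(np.dot(dh, -dir_ha))
                c0 = float(np.dot(dh, dh)) - dist ** 2
                disc = b * b - 4.0 * c0
                t = (-b + math.sqrt(max(disc, 0.0))) / 2.0
                apos = hpos + t * dir_ha
                add_molecule(dpos, donor=dpos, hydrogen=hpos)
                add_molecule(apos, acceptor=apos)
                g += 1

    frame = MolecularFrame(
        species=np.array(species, dtype=object),
        positions_nm=np.array(positions, dtype=float),
        dipoles_D=np.zeros((len(positions), 3)),
        box_nm=(box_nm, box_nm, box_nm), normal_axis="z",
        wall_positions_nm=(0.0, box_nm),
        donor_nm=np.array(donors, dtype=float),
        hydrogen_nm=np.array(hydros, dtype=float),
        acceptor_nm=np.array(acceptors, dtype=float))
    from .interfacial import hbond_count
    count, _ = hbond_count(frame)
    assert count == n_bonds, (
        f"planted {n_bonds} bonds but construction yields {count}")
    truth = {"generator": "hbond_config", "n_bonds": n_bonds,
             "n_decoys": n_decoys, "box_nm": box_nm, "seed": seed}
    return frame, truth


# ---------------------------------------------------------------------------
# Dose-response series
# ---------------------------------------------------------------------------

@dataclass
class DoseResponseSeries:
    """Pair-potential well depth vs additive bulk concentration."""

    additive: str
    c_b_M: np.ndarray  # increasing, >= 0
    w_kBT: np.ndarray  # <= 0
    w_max_kBT: float  # most negative reference depth
    notes: str = ""

    def __post_init__(self) -> None:
        self.c_b_M = np.asarray(self.c_b_M, dtype=float)
        self.w_kBT = np.asarray(self.w_kBT, dtype=float)
        if len(self.c_b_M) != len(self.w_kBT):
            raise ValueError("c_b and w must have equal length")
        if np.any(np.diff(self.c_b_M) <= 0) or np.any(self.c_b_M < 0):
            raise ValueError("concentrations must be non-negative and increasing")


@dataclass(frozen=True)
class DoseSpec:
    """Prescription for a synthetic dose–response series."""

    c_half_M: float = 0.05
    hill: float = 1.5
    noise_sd: float = 0.05  # on the normalized w/w_max scale
    n_points: int = 8
    c_range_M: Tuple[float, float] = (1e-4, 10.0)
    w_max_kBT: float = -5.0
    additive: str = "synthetic"

    def __post_init__(self) -> None:
        lo, hi = self.c_range_M
        if not (0 < lo < self.c_half_M < hi):
            raise ValueError("c_range must be positive and span c_half")
        if self.hill <= 0 or self.w_max_kBT >= 0:
            raise ValueError("hill must be > 0 and w_max < 0")


def gen_dose_series(spec: DoseSpec, seed: int = 0,
                    ) -> Tuple[DoseResponseSeries, dict]:
    """w(c) = w_max / (1 + (c/c_half)^hill) plus Gaussian noise of sd
    ``noise_sd`` on the normalized scale, at log-spaced concentrations."""
    rng = _rng(seed, "dose")
    c = np.logspace(math.log10(spec.c_range_M[0]),
                    math.log10(spec.c_range_M[1]), spec.n_points)
    f = 1.0 / (1.0 + (c / spec.c_half_M) ** spec.hill)
    if spec.noise_sd > 0:
        f = f + rng.normal(0.0, spec.noise_sd, size=len(f))
    w = spec.w_max_kBT * f
    w = np.minimum(w, 0.0)  # depths cannot be positive
    series = DoseResponseSeries(additive=spec.additive, c_b_M=c, w_kBT=w,
                                w_max_kBT=spec.w_max_kBT)
    truth = {"generator": "dose_series", "c_half_M": spec.c_half_M,
             "hill": spec.hill, "noise_sd": spec.noise_sd,
             "w_max_kBT": spec.w_max_kBT, "n_points": spec.n_points,
             "seed": seed}
    return series, truth
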