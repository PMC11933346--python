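"""Excess interfacial dipole-moment-density analysis of molecular slab frames.

The observable is the excess normal dipole moment surface density

    μ_av = ∫_{z_int}^{z_int+l} ⟨ρ(z) μ_z(z)⟩ dz − ∫_bulk (same, thickness l),

where ⟨ρ(z) μ_z(z)⟩ is the laterally- and time-averaged density of the
normal dipole component at distance z from the wall, z_int locates the
interfacial plane, and l is the interfacial thickness.  μ_av is reported in
D nm⁻²; the equivalent interfacial potential is φ_int = −μ_av/ε₀.  Profiles
are computed per wall with the surface normal pointing *into* the liquid, so
the two sides of a slab can be averaged directly; their half-difference
serves as the convergence uncertainty.

Frames carry a precomputed binning position and molecular dipole per
molecule (for water the convention is to bin at the O atom; other species at
their centre of geometry — the responsibility of whatever produced the
frame), keeping this module force-field-agnostic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy.spatial import cKDTree

from .media import DEBYE, NM_TO_M, VACUUM_PERMITTIVITY

__all__ = [
    "MolecularFrame", "DipoleDensityProfile", "MuAvResult",
    "dipole_profile", "detect_interface", "mu_av",
    "continuum_polarization", "hbond_count",
    "read_exyz", "write_exyz",
]

_AXIS = {"x": 0, "y": 1, "z": 2}


@dataclass
class MolecularFrame:
    """One snapshot of molecules between two walls.

    ``positions_nm`` are the per-molecule binning positions, ``dipoles_D``
    the molecular dipole vectors.  ``wall_positions_nm`` are the two wall
    coordinates along ``normal_axis`` (lower < upper).  Hydrogen-bond
    geometry (donor, hydrogen, acceptor atom positions) is optional and
    NaN-filled where a molecule lacks the corresponding site.
    """

    species: np.ndarray  # (N,) str
    positions_nm: np.ndarray  # (N, 3)
    dipoles_D: np.ndarray  # (N, 3)
    box_nm: Tuple[float, float, float]
    normal_axis: str = "z"
    wall_positions_nm: Tuple[float, float] = (0.0, 0.0)
    donor_nm: Optional[np.ndarray] = None
    hydrogen_nm: Optional[np.ndarray] = None
    acceptor_nm: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.species = np.asarray(self.species, dtype=object)
        self.positions_nm = np.asarray(self.positions_nm, dtype=float).reshape(-1, 3)
        self.dipoles_D = np.asarray(self.dipoles_D, dtype=float).reshape(-1, 3)
        n = len(self.species)
        if not (self.positions_nm.shape[0] == self.dipoles_D.shape[0] == n):
            raise ValueError("species, positions and dipoles must share length")
        if self.normal_axis not in _AXIS:
            raise ValueError(f"normal_axis must be x, y or z, got {self.normal_axis}")
        lo, hi = self.wall_positions_nm
        if hi <= lo:
            raise ValueError("wall positions must be ordered along the normal axis")
        ax = _AXIS[self.normal_axis]
        zs = self.positions_nm[:, ax]
        if n and (zs.min() < -1e-9 or zs.max() > self.box_nm[ax] + 1e-9):
            raise ValueError("binning positions must lie inside the box")

    def __len__(self) -> int:
        return len(self.species)

    @property
    def axis_index(self) -> int:
        return _AXIS[self.normal_axis]

    @property
    def slab_thickness_nm(self) -> float:
        lo, hi = self.wall_positions_nm
        return hi - lo


@dataclass
class DipoleDensityProfile:
    """Binned ⟨ρ(z) μ_z(z)⟩ against distance z from one wall (D nm⁻³).

    The profile is expressed in the wall's own frame: z grows into the
    liquid and μ_z is the dipole component along the inward normal, so
    profiles from opposite walls are directly comparable.
    """

    z_centers_nm: np.ndarray
    p: np.ndarray
    bin_width_nm: float
    n_frames: int
    side: str  # "lower" | "upper"
    bulk_value: float = 0.0
    bulk_window_nm: Tuple[float, float] = (0.0, 0.0)
    species_filter: str = "all"

    def __post_init__(self) -> None:
        self.z_centers_nm = np.asarray(self.z_centers_nm, dtype=float)
        self.p = np.asarray(self.p, dtype=float)
        if len(self.z_centers_nm) != len(self.p):
            raise ValueError("z_centers and p must have equal length")


@dataclass
class MuAvResult:
    """Excess interfacial dipole density averaged over both walls."""

    mu_av: float  # D nm^-2
    mu_av_per_interface: Tuple[float, float]
    uncertainty: float  # half |difference of sides|
    phi_int_V: float
    z_int_nm: float
    l_nm: float
    species_filter: str = "all"


# ---------------------------------------------------------------------------
# Profiles
# ---------------------------------------------------------------------------

def dipole_profile(frames: Sequence[MolecularFrame], bin_width_nm: float = 0.02,
                   species_filter: str = "all", side: str = "lower",
                   ) -> DipoleDensityProfile:
    """Bin the normal dipole component density against distance from one wall.

    Each bin accumulates Σ μ·n over molecules whose binning position falls
    inside the slab [z, z+Δz), divided by the slab volume and the number of
    frames.  ``side`` selects the wall; the normal always points into the
    liquid (so the "upper" profile has its dipole components sign-flipped).
    ``species_filter`` restricts to one species ("all" keeps everything).
    """
    frames = list(frames)
    if not frames:
        raise ValueError("at least one frame is required")
    if bin_width_nm <= 0:
        raise ValueError("bin_width_nm must be positive")
    if side not in ("lower", "upper"):
        raise ValueError(f"side must be 'lower' or 'upper', got {side!r}")
    f0 = frames[0]
    ax = f0.axis_index
    lo, hi = f0.wall_positions_nm
    H = hi - lo
    n_bins = int(math.ceil(H / bin_width_nm))
    edges = np.arange(n_bins + 1) * bin_width_nm
    lateral = [f0.box_nm[i] for i in range(3) if i != ax]
    slab_volume = lateral[0] * lateral[1] * bin_width_nm

    acc = np.zeros(n_bins)
    total_selected = 0
    for fr in frames:
        if fr.wall_positions_nm != f0.wall_positions_nm or fr.box_nm != f0.box_nm:
            raise ValueError("all frames must share box and wall geometry")
        zs = fr.positions_nm[:, ax]
        mu = fr.dipoles_D[:, ax]
        if side == "lower":
            d = zs - lo
        else:
            d = hi - zs
            mu = -mu
        if species_filter != "all":
            sel = fr.species == species_filter
            if not np.any(sel):
                raise ValueError(
                    f"species filter {species_filter!r} selects no molecules"
                )
            d, mu = d[sel], mu[sel]
        total_selected += len(d)
        idx = np.floor(d / bin_width_nm).astype(int)
        ok = (idx >= 0) & (idx < n_bins)
        np.add.at(acc, idx[ok], mu[ok])
    p = acc / (slab_volume * len(frames))
    centers = 0.5 * (edges[:-1] + edges[1:])

    # bulk: central 20% of the slab by default
    bulk_lo, bulk_hi = 0.4 * H, 0.6 * H
    in_bulk = (centers >= bulk_lo) & (centers <= bulk_hi)
    bulk_value = float(p[in_bulk].mean()) if np.any(in_bulk) else 0.0
    return DipoleDensityProfile(z_centers_nm=centers, p=p,
                                bin_width_nm=bin_width_nm, n_frames=len(frames),
                                side=side, bulk_value=bulk_value,
                                bulk_window_nm=(bulk_lo, bulk_hi),
                                species_filter=species_filter)


def detect_interface(profile: DipoleDensityProfile,
                     bulk_window_nm: Optional[Tuple[float, float]] = None,
                     decay_tolerance: float = 0.05,
                     ) -> Tuple[float, float]:
    """Locate the interfacial plane and thickness from a dipole profile.

    z_int is the first bin, scanning from the wall, where p crosses the bulk
    value; l is the smallest distance beyond which |p − bulk| stays within
    ``decay_tolerance`` × max|p − bulk| out to the bulk window.  A profile
    that never settles to bulk raises (the slab is too thin).
    """
    z = profile.z_centers_nm
    p = profile.p
    if bulk_window_nm is None:
        bulk_window_nm = profile.bulk_window_nm
    blo, bhi = bulk_window_nm
    in_bulk = (z >= blo) & (z <= bhi)
    if not np.any(in_bulk):
        raise ValueError("bulk window selects no bins")
    bulk = float(p[in_bulk].mean())

    dev = p - bulk
    scan = z < blo
    if not np.any(scan):
        raise ValueError("no bins between wall and bulk window")
    dev_scan = dev[scan]
    z_scan = z[scan]
    max_dev = float(np.max(np.abs(dev_scan)))
    if max_dev == 0.0:
        # degenerate: flat profile equal to bulk everywhere
        return float(z_scan[0]), float(profile.bin_width_nm)

    # first crossing of the bulk value (sign change or touch of dev)
    sign0 = math.copysign(1.0, dev_scan[0]) if dev_scan[0] != 0 else 0.0
    z_int = float(z_scan[0])
    for k in range(len(dev_scan)):
        if dev_scan[k] == 0.0 or math.copysign(1.0, dev_scan[k]) != sign0:
            z_int = float(z_scan[k])
            break

    # decay distance of the oscillations
    tol = decay_tolerance * max_dev
    settled = np.abs(dev_scan) < tol
    l = float(z_scan[-1] - z_scan[0] + profile.bin_width_nm)
    for k in range(len(dev_scan)):
        if np.all(settled[k:]):
            l = max(float(z_scan[k] - z_int), profile.bin_width_nm)
            break
    else:
        raise ValueError(
            "profile oscillations never decay to the bulk value before the "
            "bulk window; a larger box (thicker slab) is required"
        )
    return z_int, l


def _window_integral(profile: DipoleDensityProfile, a: float, b: float) -> float:
    """Trapezoidal ∫ p dz over [a, b], linearly interpolating the binned
    profile at the window edges."""
    if b <= a:
        raise ValueError("integration window must have positive width")
    z, p = profile.z_centers_nm, profile.p
    grid = np.union1d(z[(z > a) & (z < b)], [a, b])
    vals = np.interp(grid, z, p)
    return float(np.trapezoid(vals, grid))


def mu_av(profile_lower: DipoleDensityProfile,
          profile_upper: DipoleDensityProfile,
          z_int_nm: float, l_nm: float,
          bulk_window_nm: Optional[Tuple[float, float]] = None,
          ) -> MuAvResult:
    """Excess dipole surface density from the two single-wall profiles.

    Per side: ∫_{z_int}^{z_int+l} p dz − ∫_{bulk} p dz (same thickness l,
    placed at the start of the bulk window).  The sides are averaged; the
    half-difference is the reported uncertainty.  φ_int = −μ_av/ε₀.
    """
    if profile_lower.bin_width_nm != profile_upper.bin_width_nm or \
            len(profile_lower.p) != len(profile_upper.p):
        raise ValueError("the two side profiles must share binning")
    if bulk_window_nm is None:
        bulk_window_nm = profile_lower.bulk_window_nm
    blo, bhi = bulk_window_nm
    if z_int_nm + l_nm > blo + 1e-9:
        raise ValueError(
            f"interfacial window [{z_int_nm}, {z_int_nm + l_nm}] nm reaches "
            f"into the bulk window starting at {blo} nm"
        )
    per_side = []
    for prof in (profile_lower, profile_upper):
        intf = _window_integral(prof, z_int_nm, z_int_nm + l_nm)
        bulk = _window_integral(prof, blo, blo + l_nm)
        per_side.append(intf - bulk)
    mu = 0.5 * (per_side[0] + per_side[1])
    unc = 0.5 * abs(per_side[0] - per_side[1])
    phi = -mu * DEBYE / NM_TO_M ** 2 / VACUUM_PERMITTIVITY
    return MuAvResult(mu_av=mu, mu_av_per_interface=(per_side[0], per_side[1]),
                      uncertainty=unc, phi_int_V=phi, z_int_nm=z_int_nm,
                      l_nm=l_nm, species_filter=profile_lower.species_filter)


def continuum_polarization(sigma_e_nm2: float, epsilon_r: float) -> float:
    """Midplane polarization of a charged capacitor with a continuum
    dielectric: P = σ (ε − 1)/ε, in e nm⁻² (the bound-charge density the
    dielectric builds up to screen the plates)."""
    if epsilon_r <= 1:
        raise ValueError(f"epsilon_r must exceed 1, got {epsilon_r}")
    return sigma_e_nm2 * (epsilon_r - 1.0) / epsilon_r


# ---------------------------------------------------------------------------
# Hydrogen-bond counting
# ---------------------------------------------------------------------------

HBOND_DISTANCE_NM = 0.3  # donor-acceptor distance criterion (3 A)
HBOND_ANGLE_DEG = 150.0  # donor-H-acceptor angle criterion


def hbond_count(frame: MolecularFrame,
                distance_nm: float = HBOND_DISTANCE_NM,
                angle_deg: float = HBOND_ANGLE_DEG,
                ) -> Tuple[int, List[Tuple[int, int]]]:
    """Count hydrogen bonds between molecules by the geometric criterion:
    d(donor, acceptor) < ``distance_nm`` and donor–H–acceptor angle >
    ``angle_deg``, with minimum-image distances.

    Returns (count, list of (donor molecule, acceptor molecule) pairs).
    Donor and hydrogen sites must be present together; molecules with a
    donor but no hydrogen are reported as an error.
    """
    if frame.donor_nm is None or frame.acceptor_nm is None:
        return 0, []
    donors = np.asarray(frame.donor_nm, dtype=float).reshape(-1, 3)
    acceptors = np.asarray(frame.acceptor_nm, dtype=float).reshape(-1, 3)
    if frame.hydrogen_nm is None:
        hydro = np.full_like(donors, np.nan)
    else:
        hydro = np.asarray(frame.hydrogen_nm, dtype=float).reshape(-1, 3)
    has_d = ~np.isnan(donors).any(axis=1)
    has_h = ~np.isnan(hydro).any(axis=1)
    missing = np.nonzero(has_d & ~has_h)[0]
    if missing.size:
        raise ValueError(
            "molecules with a donor but no hydrogen coordinate: "
            f"{missing.tolist()}"
        )
    has_a = ~np.isnan(acceptors).any(axis=1)
    d_idx = np.nonzero(has_d)[0]
    a_idx = np.nonzero(has_a)[0]
    if d_idx.size == 0 or a_idx.size == 0:
        return 0, []

    box = np.asarray(frame.box_nm, dtype=float)
    dw = np.mod(donors[d_idx], box)
    aw = np.mod(acceptors[a_idx], box)
    tree_a = cKDTree(aw, boxsize=box)
    neigh = cKDTree(dw, boxsize=box).query_ball_tree(tree_a, r=distance_nm)

    cos_cut = math.cos(math.radians(angle_deg))
    pairs: List[Tuple[int, int]] = []
    for di_local, cand in enumerate(neigh):
        di = d_idx[di_local]
        for aj_local in cand:
            aj = a_idx[aj_local]
            if aj == di:
                continue
            # minimum-image separation check is already guaranteed by the tree;
            # recompute vectors for the angle with minimum image
            vda = aw[aj_local] - dw[di_local]
            vda -= box * np.round(vda / box)
            if np.dot(vda, vda) >= distance_nm ** 2:
                continue
            h = hydro[di]
            vhd = donors[di] - h
            vha = (acceptors[aj] - h)
            vha -= box * np.round(vha / box)
            vhd -= box * np.round(vhd / box)
            nd = np.linalg.norm(vhd)
            na = np.linalg.norm(vha)
            if nd == 0 or na == 0:
                continue
            cang = float(np.dot(vhd, vha) / (nd * na))
            # angle(D-H...A) > angle_deg  <=>  cos(angle) < cos(angle_deg)
            if cang < cos_cut:
                pairs.append((int(di), int(aj)))
    return len(pairs), pairs


# ---------------------------------------------------------------------------
# Extended-XYZ frame files
# ---------------------------------------------------------------------------

_EXYZ_COLS = "species:S:1:pos:R:3:dipole:R:3:donor:R:3:hydrogen:R:3:acceptor:R:3"


def write_exyz(frames: Sequence[MolecularFrame], path: str) -> None:
    """Write frames to an extended-XYZ dialect (nm / Debye units).

    The comment line carries box, normal axis and wall metadata as
    key=value pairs; per-molecule columns are species, binning position,
    dipole vector and the optional H-bond sites (nan where absent).
    """
    with open(path, "w") as fh:
        for fr in frames:
            n = len(fr)
            fh.write(f"{n}\n")
            bx, by, bz = fr.box_nm
            w0, w1 = fr.wall_positions_nm
            fh.write(
                f'box="{bx:.17g} {by:.17g} {bz:.17g}" '
                f'normal_axis={fr.normal_axis} walls="{w0:.17g} {w1:.17g}" '
                f'Properties={_EXYZ_COLS}\n'
            )
            donor = fr.donor_nm if fr.donor_nm is not None else np.full((n, 3), np.nan)
            hyd = fr.hydrogen_nm if fr.hydrogen_nm is not None else np.full((n, 3), np.nan)
            acc = fr.acceptor_nm if fr.acceptor_nm is not None else np.full((n, 3), np.nan)
            for i in range(n):
                row = [str(fr.species[i])]
                for arr in (fr.positions_nm, fr.dipoles_D, donor, hyd, acc):
                    row.extend(f"{v:.17g}" for v in arr[i])
                fh.write(" ".join(row) + "\n")


def read_exyz(path: str) -> List[MolecularFrame]:
    """Read frames written by :func:`write_exyz` (bit-stable round trip)."""
    frames: List[MolecularFrame] = []
    with open(path) as fh:
        lines = fh.read().splitlines()
    k = 0
    while k < len(lines):
        if not lines[k].strip():
            k += 1
            continue
        n = int(lines[k].strip())
        meta = lines[k + 1]
        kv = {}
        import re
        for m in re.finditer(r'(\w+)=(?:"([^"]*)"|(\S+))', meta):
            kv[m.group(1)] = m.group(2) if m.group(2) is not None else m.group(3)
        box = tuple(float(v) for v in kv["box"].split())
        walls = tuple(float(v) for v in kv["walls"].split())
        axis = kv.get("normal_axis", "z")
        species = []
        data = np.empty((n, 15))
        for i in range(n):
            parts = lines[k + 2 + i].split()
            species.append(parts[0])
            data[i] = [float(v) for v in parts[1:16]]
        frames.append(MolecularFrame(
            species=np.array(species, dtype=object),
            positions_nm=data[:, 0:3], dipoles_D=data[:, 3:6],
            box_nm=box, normal_axis=axis, wall_positions_nm=walls,
            donor_nm=data[:, 6:9], hydrogen_nm=data[:, 9:12],
            acceptor_nm=data[:, 12:15],
        ))
        k += 2 + n
    return frames
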