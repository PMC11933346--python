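"""Structural analysis of 2-D particle ensembles: radial distribution
functions, peak analysis, disc rendering and centroid localization.

g(r) here is the standard 2-D pair correlation: the density of interparticle
separations relative to an ideal gas at the same number density, estimated
with minimum-image distances and the analytic 2πrΔr shell normalization
(valid for r ≤ L/2 in a periodic box).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy.signal import find_peaks

from .bdsim import Ensemble

__all__ = [
    "RadialDistribution", "DiscImage",
    "radial_distribution", "first_peak", "render_discs", "locate_particles",
]


@dataclass
class RadialDistribution:
    """Binned g(r) with its normalization metadata.

    ``counts`` holds the raw per-bin pair counts summed over frames, so the
    bookkeeping identity Σ_bins g·ρ·2πr·Δr·(N/2)·n_frames = Σ counts holds
    exactly and downstream fits can weight bins by their statistics.
    """

    r_centers_um: np.ndarray
    g: np.ndarray
    bin_width_um: float
    n_particles: int
    number_density_per_um2: float
    n_frames: int
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.r_centers_um = np.asarray(self.r_centers_um, dtype=float)
        self.g = np.asarray(self.g, dtype=float)
        self.counts = np.asarray(self.counts, dtype=float)
        if not (len(self.r_centers_um) == len(self.g) == len(self.counts)):
            raise ValueError("r_centers, g and counts must have equal length")
        if np.any(self.g < 0):
            raise ValueError("g(r) must be non-negative")

    @property
    def r_max_um(self) -> float:
        return float(self.r_centers_um[-1] + self.bin_width_um / 2)

    def interpolate(self, r_um: np.ndarray) -> np.ndarray:
        """Linear interpolation of g onto new radii (1.0 outside support)."""
        return np.interp(r_um, self.r_centers_um, self.g, left=0.0, right=1.0)


def radial_distribution(frames: Sequence[Ensemble], r_max_um: float,
                        bin_width_um: float = 0.1) -> RadialDistribution:
    """Estimate g(r) from one or more ensemble frames.

    Every frame must share box size and particle count.  For periodic
    frames, pairs are counted with minimum-image distances and the
    normalization divides the mean pair count per bin by
    N·ρ·π·((r+Δ)² − r²)/2 — the expected ideal-gas count — so a uniform
    random ensemble gives g ≈ 1 everywhere.  Non-periodic frames (an
    experimental field of view) use a guard-region correction instead:
    only particles at least ``r_max_um`` from every border act as centres,
    each paired against all particles, so no shell is ever clipped.
    """
    frames = list(frames)
    if not frames:
        raise ValueError("at least one frame is required")
    L = frames[0].box_length_um
    N = len(frames[0])
    if r_max_um > L / 2 + 1e-12:
        raise ValueError(
            f"r_max {r_max_um} um exceeds box_length/2 = {L / 2} um; beyond "
            "that radius periodic images alias the pair distances"
        )
    n_bins = int(round(r_max_um / bin_width_um))
    edges = np.arange(n_bins + 1) * bin_width_um
    counts = np.zeros(n_bins)
    n_center_frames = 0.0  # Σ over frames of the number of centre particles
    block = max(1, min(N, int(2e7 // max(N, 1))))  # cap temp arrays ~300 MB
    for fr in frames:
        if fr.box_length_um != L or len(fr) != N:
            raise ValueError("all frames must share box size and particle count")
        p = fr.positions
        if fr.periodic:
            n_center_frames += N
            for i0 in range(0, N, block):
                i1 = min(i0 + block, N)
                d = p[i0:i1, None, :] - p[None, i0:, :]
                d -= L * np.round(d / L)
                r = np.sqrt((d ** 2).sum(-1))
                # keep each unordered pair once: global column > global row
                mask = (np.arange(i0, N)[None, :]
                        > np.arange(i0, i1)[:, None])
                h, _ = np.histogram(r[mask], bins=edges)
                counts += h
        else:
            # guard region: centres with a full unclipped shell
            interior = np.all((p >= r_max_um) & (p <= L - r_max_um), axis=1)
            centers_p = p[interior]
            n_center_frames += len(centers_p)
            for i0 in range(0, len(centers_p), block):
                i1 = min(i0 + block, len(centers_p))
                d = centers_p[i0:i1, None, :] - p[None, :, :]
                r = np.sqrt((d ** 2).sum(-1))
                h, _ = np.histogram(r[r > 0], bins=edges)
                counts += h
    rho = N / L ** 2
    r_lo = edges[:-1]
    r_hi = edges[1:]
    shell = math.pi * (r_hi ** 2 - r_lo ** 2)  # 2π r Δr, exactly
    if frames[0].periodic:
        ideal = 0.5 * rho * shell * n_center_frames
    else:
        ideal = rho * shell * n_center_frames  # ordered centre->all counts
    g = np.divide(counts, ideal, out=np.zeros_like(counts), where=ideal > 0)
    centers = 0.5 * (r_lo + r_hi)
    return RadialDistribution(r_centers_um=centers, g=g,
                              bin_width_um=bin_width_um, n_particles=N,
                              number_density_per_um2=rho, n_frames=len(frames),
                              counts=counts)


def first_peak(rdf: RadialDistribution,
               min_prominence: float = 0.3) -> Optional[float]:
    """Location (μm) of the first local maximum of g(r) with the given
    prominence, or None for a featureless/monotone profile.

    For a clustering suspension this peak sits at the preferred
    centre-to-centre distance 2R + x_min and initializes the potential
    inference.
    """
    idx, _ = find_peaks(rdf.g, prominence=min_prominence)
    if idx.size == 0:
        return None
    return float(rdf.r_centers_um[idx[0]])


# ---------------------------------------------------------------------------
# Rendering and localization
# ---------------------------------------------------------------------------

@dataclass
class DiscImage:
    """Grayscale image of rendered discs; intensities in [0, 1].

    ``origin_um`` maps pixel (row, col) = (0, 0) to physical coordinates:
    x = origin_x + (col + 0.5)·pixel_size, y = origin_y + (row + 0.5)·pixel_size.
    """

    pixels: np.ndarray
    pixel_size_um: float
    origin_um: Tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        if self.pixels.size and (self.pixels.min() < 0 or self.pixels.max() > 1):
            raise ValueError("intensities must lie in [0, 1]")


def render_discs(ensemble: Ensemble, pixel_size_um: float,
                 supersample: int = 4) -> DiscImage:
    """Render the ensemble as anti-aliased filled discs on a zero background.

    Each pixel's intensity is the sub-pixel coverage fraction of the disc,
    estimated on a ``supersample``× finer grid, so the integrated intensity
    approximates the true disc area πR²/pixel_size².
    """
    if pixel_size_um <= 0:
        raise ValueError("pixel_size_um must be positive")
    L = ensemble.box_length_um
    n_px = max(1, int(math.ceil(L / pixel_size_um)))
    img = np.zeros((n_px, n_px))
    if len(ensemble) == 0:
        return DiscImage(pixels=img, pixel_size_um=pixel_size_um)
    s = supersample
    centres = []
    for (cx, cy), R in zip(ensemble.positions, ensemble.radii):
        centres.append((cx, cy, R))
        if ensemble.periodic:
            # draw periodic images of discs straddling the box boundary
            for ox in (-L, 0.0, L):
                for oy in (-L, 0.0, L):
                    if ox == 0.0 and oy == 0.0:
                        continue
                    px_, py_ = cx + ox, cy + oy
                    if -R <= px_ <= L + R and -R <= py_ <= L + R:
                        centres.append((px_, py_, R))
    for cx, cy, R in centres:
        r_px = R / pixel_size_um
        col_c = cx / pixel_size_um - 0.5
        row_c = cy / pixel_size_um - 0.5
        lo_r = max(0, int(math.floor(row_c - r_px - 1)))
        hi_r = min(n_px, int(math.ceil(row_c + r_px + 2)))
        lo_c = max(0, int(math.floor(col_c - r_px - 1)))
        hi_c = min(n_px, int(math.ceil(col_c + r_px + 2)))
        if lo_r >= hi_r or lo_c >= hi_c:
            continue
        # supersampled subpixel centres within the bounding box
        sub = (np.arange(s) + 0.5) / s - 0.5
        rows = np.arange(lo_r, hi_r)[:, None] + sub[None, :]
        cols = np.arange(lo_c, hi_c)[:, None] + sub[None, :]
        dr2 = (rows - row_c) ** 2  # (nr, s)
        dc2 = (cols - col_c) ** 2  # (nc, s)
        inside = (dr2[:, None, :, None] + dc2[None, :, None, :]) <= r_px ** 2
        cover = inside.reshape(hi_r - lo_r, hi_c - lo_c, s * s).mean(axis=2)
        img[lo_r:hi_r, lo_c:hi_c] = np.maximum(img[lo_r:hi_r, lo_c:hi_c], cover)
    return DiscImage(pixels=np.clip(img, 0.0, 1.0), pixel_size_um=pixel_size_um)


def locate_particles(image: DiscImage, threshold: Optional[float] = None,
                     min_area_px: int = 3) -> np.ndarray:
    """Detect particle centres as intensity-weighted centroids of connected
    components above threshold (Otsu by default).  Returns (K, 2) positions
    in μm; an empty array (with a warning) for blank or saturated images.
    """
    from skimage.filters import threshold_otsu
    from skimage.measure import label, regionprops

    px = image.pixels
    if px.size == 0 or np.ptp(px) == 0.0:
        import warnings
        warnings.warn("blank or saturated image: no particles located")
        return np.empty((0, 2))
    if threshold is None:
        threshold = float(threshold_otsu(px))
    mask = px > threshold
    lab = label(mask)
    out: List[Tuple[float, float]] = []
    for region in regionprops(lab, intensity_image=px):
        if region.area < min_area_px:
            continue
        row, col = region.centroid_weighted
        x = image.origin_um[0] + (col + 0.5) * image.pixel_size_um
        y = image.origin_um[1] + (row + 0.5) * image.pixel_size_um
        out.append((x, y))
    if not out:
        import warnings
        warnings.warn("no component above threshold: no particles located")
        return np.empty((0, 2))
    return np.asarray(out)
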