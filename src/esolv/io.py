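"""Run configuration and the package's table/frame file dialects.

All file schemas are plain text (CSV with ``#`` metadata headers, JSON,
YAML) and carry a ``format_version`` so they can evolve; trajectories may
additionally be archived as HDF5.  Write→read round-trips are identities.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from typing import Any, Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .bdsim import Ensemble, SimulationConfig
from .structure import RadialDistribution
from .synthetic import DoseResponseSeries

FORMAT_VERSION = 1

__all__ = [
    "RunConfig", "load_config", "dump_config",
    "write_ensemble_csv", "read_ensemble_csv",
    "write_gr_csv", "read_gr_csv",
    "write_dose_csv", "read_dose_csv",
    "save_trajectory_h5", "load_trajectory_h5",
]


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

_SIM_KEYS = {"box_length_um": float, "number_density_per_um2": float,
             "radius_mean_um": float, "radius_sd_um": float,
             "diffusion_um2_s": float, "timestep_s": float,
             "n_steps": int, "sample_interval": int,
             "interaction_cutoff_um": float, "x_floor_um": float}
_POT_KEYS = {"w_kBT": float, "x_min_um": float, "kappa1_per_um": float,
             "kappa_ratio": float}
_INFER_KEYS = {"x_halfwidth_um": float, "x_step_um": float,
               "min_prominence": float, "refine": bool}
_TOP_KEYS = {"format_version": int, "seed": int, "output_dir": str,
             "log_level": str, "simulation": dict, "potential": dict,
             "inference": dict}


@dataclass
class RunConfig:
    """Validated, defaults-filled run configuration."""

    seed: int = 0
    output_dir: str = "."
    log_level: str = "INFO"
    simulation: Dict[str, Any] = field(default_factory=dict)
    potential: Dict[str, Any] = field(default_factory=dict)
    inference: Dict[str, Any] = field(default_factory=dict)
    format_version: int = FORMAT_VERSION

    def simulation_config(self, **overrides: Any) -> SimulationConfig:
        kw = dict(self.simulation)
        kw.update(overrides)
        kw.setdefault("seed", self.seed)
        return SimulationConfig(**kw)

    def to_dict(self) -> Dict[str, Any]:
        return {"format_version": self.format_version, "seed": self.seed,
                "output_dir": self.output_dir, "log_level": self.log_level,
                "simulation": dict(self.simulation),
                "potential": dict(self.potential),
                "inference": dict(self.inference)}


def _check_keys(section: str, data: Dict[str, Any],
                allowed: Dict[str, type]) -> None:
    for key, value in data.items():
        if key not in allowed:
            raise ValueError(
                f"unknown configuration key {section}.{key!r}; allowed: "
                f"{sorted(allowed)}"
            )
        want = allowed[key]
        if value is None:
            continue
        if want in (float, int) and not isinstance(value, (int, float)):
            raise ValueError(
                f"configuration key {section}.{key!r} must be numeric, "
                f"got {type(value).__name__}"
            )
        if want is str and not isinstance(value, str):
            raise ValueError(f"configuration key {section}.{key!r} must be text")
        if want is bool and not isinstance(value, bool):
            raise ValueError(f"configuration key {section}.{key!r} must be boolean")
        if want is dict and not isinstance(value, dict):
            raise ValueError(f"configuration key {section}.{key!r} must be a mapping")


def load_config(path: str) -> RunConfig:
    """Load and validate a YAML/JSON run configuration; unknown keys are
    rejected with the offending path named."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"configuration root must be a mapping, got {type(raw)}")
    _check_keys("<root>", raw, _TOP_KEYS)
    _check_keys("simulation", raw.get("simulation") or {}, _SIM_KEYS)
    _check_keys("potential", raw.get("potential") or {}, _POT_KEYS)
    _check_keys("inference", raw.get("inference") or {}, _INFER_KEYS)
    return RunConfig(
        seed=int(raw.get("seed", 0)),
        output_dir=str(raw.get("output_dir", ".")),
        log_level=str(raw.get("log_level", "INFO")),
        simulation=dict(raw.get("simulation") or {}),
        potential=dict(raw.get("potential") or {}),
        inference=dict(raw.get("inference") or {}),
        format_version=int(raw.get("format_version", FORMAT_VERSION)),
    )


def dump_config(config: RunConfig, path: str) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)


# ---------------------------------------------------------------------------
# Ensemble snapshots
# ---------------------------------------------------------------------------

def write_ensemble_csv(ensemble: Ensemble, path: str,
                       step: Optional[int] = None,
                       seed: Optional[int] = None) -> None:
    """CSV snapshot (id, x_um, y_um, radius_um) with a JSON sidecar carrying
    box size, step and seed."""
    df = pd.DataFrame({
        "id": np.arange(len(ensemble)),
        "x_um": ensemble.positions[:, 0],
        "y_um": ensemble.positions[:, 1],
        "radius_um": ensemble.radii,
    })
    df.to_csv(path, index=False, float_format="%.10g")
    sidecar = {"format_version": FORMAT_VERSION,
               "box_length_um": ensemble.box_length_um,
               "periodic": ensemble.periodic, "step": step, "seed": seed}
    with open(path + ".json", "w") as fh:
        json.dump(sidecar, fh, indent=1)


def read_ensemble_csv(path: str) -> Ensemble:
    df = _read_csv_strict(path)
    with open(path + ".json") as fh:
        sidecar = json.load(fh)
    return Ensemble(positions=df[["x_um", "y_um"]].to_numpy(),
                    radii=df["radius_um"].to_numpy(),
                    box_length_um=float(sidecar["box_length_um"]))


def _read_csv_strict(path: str) -> pd.DataFrame:
    """CSV reader that reports the offending line on malformed rows."""
    try:
        return pd.read_csv(path, comment="#", on_bad_lines="error")
    except pd.errors.ParserError as err:
        raise ValueError(f"malformed CSV {path}: {err}") from err


# ---------------------------------------------------------------------------
# g(r) tables
# ---------------------------------------------------------------------------

def write_gr_csv(rdf: RadialDistribution, path: str) -> None:
    """g(r) table (r_um, g, counts) with normalization metadata in ``#``
    header lines."""
    with open(path, "w") as fh:
        fh.write(f"# format_version={FORMAT_VERSION}\n")
        fh.write(f"# n_particles={rdf.n_particles}\n")
        fh.write(f"# number_density_per_um2={rdf.number_density_per_um2:.12g}\n")
        fh.write(f"# bin_width_um={rdf.bin_width_um:.12g}\n")
        fh.write(f"# n_frames={rdf.n_frames}\n")
        fh.write("r_um,g,counts\n")
        for r, g, c in zip(rdf.r_centers_um, rdf.g, rdf.counts):
            fh.write(f"{r:.10g},{g:.10g},{c:.10g}\n")


def read_gr_csv(path: str) -> RadialDistribution:
    meta: Dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            key, _, value = line[1:].strip().partition("=")
            meta[key.strip()] = value.strip()
    df = _read_csv_strict(path)
    return RadialDistribution(
        r_centers_um=df["r_um"].to_numpy(), g=df["g"].to_numpy(),
        counts=df["counts"].to_numpy(),
        bin_width_um=float(meta["bin_width_um"]),
        n_particles=int(meta["n_particles"]),
        number_density_per_um2=float(meta["number_density_per_um2"]),
        n_frames=int(meta["n_frames"]))


# ---------------------------------------------------------------------------
# Dose-response tables
# ---------------------------------------------------------------------------

def write_dose_csv(series: DoseResponseSeries, path: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# format_version={FORMAT_VERSION}\n")
        fh.write(f"# w_max_kBT={series.w_max_kBT:.10g}\n")
        fh.write("additive,c_b_M,w_kBT\n")
        for c, w in zip(series.c_b_M, series.w_kBT):
            fh.write(f"{series.additive},{c:.10g},{w:.10g}\n")


def read_dose_csv(path: str) -> DoseResponseSeries:
    meta: Dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            key, _, value = line[1:].strip().partition("=")
            meta[key.strip()] = value.strip()
    df = _read_csv_strict(path)
    additives = df["additive"].unique()
    if len(additives) != 1:
        raise ValueError("dose table must describe exactly one additive")
    return DoseResponseSeries(additive=str(additives[0]),
                              c_b_M=df["c_b_M"].to_numpy(),
                              w_kBT=df["w_kBT"].to_numpy(),
                              w_max_kBT=float(meta["w_max_kBT"]))


# ---------------------------------------------------------------------------
# Disc images
# ---------------------------------------------------------------------------

def save_disc_image(image, path: str) -> None:
    """Write a rendered disc image as 16-bit grayscale (TIFF or PNG by
    extension) with the pixel size in a JSON metadata sidecar."""
    import imageio.v3 as iio

    from .structure import DiscImage

    assert isinstance(image, DiscImage)
    px16 = np.round(np.clip(image.pixels, 0.0, 1.0) * 65535).astype(np.uint16)
    iio.imwrite(path, px16)
    with open(path + ".json", "w") as fh:
        json.dump({"format_version": FORMAT_VERSION,
                   "pixel_size_um": image.pixel_size_um,
                   "origin_um": list(image.origin_um)}, fh, indent=1)


def load_disc_image(path: str):
    """Read an image written by :func:`save_disc_image`."""
    import imageio.v3 as iio

    from .structure import DiscImage

    px = np.asarray(iio.imread(path), dtype=float) / 65535.0
    with open(path + ".json") as fh:
        meta = json.load(fh)
    return DiscImage(pixels=px, pixel_size_um=float(meta["pixel_size_um"]),
                     origin_um=tuple(meta.get("origin_um", (0.0, 0.0))))


# ---------------------------------------------------------------------------
# Trajectory archives
# ---------------------------------------------------------------------------

def save_trajectory_h5(frames: Sequence[Ensemble], path: str,
                       seed: Optional[int] = None) -> None:
    """Multi-frame trajectory archive (HDF5)."""
    import h5py

    frames = list(frames)
    if not frames:
        raise ValueError("no frames to save")
    with h5py.File(path, "w") as h5:
        h5.attrs["format_version"] = FORMAT_VERSION
        h5.attrs["box_length_um"] = frames[0].box_length_um
        if seed is not None:
            h5.attrs["seed"] = seed
        h5.create_dataset("positions",
                          data=np.stack([f.positions for f in frames]))
        h5.create_dataset("radii", data=frames[0].radii)


def load_trajectory_h5(path: str) -> List[Ensemble]:
    import h5py

    with h5py.File(path, "r") as h5:
        pos = np.asarray(h5["positions"])
        radii = np.asarray(h5["radii"])
        L = float(h5.attrs["box_length_um"])
    return [Ensemble(positions=pos[k], radii=radii, box_length_um=L)
            for k in range(pos.shape[0])]
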