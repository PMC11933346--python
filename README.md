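# esolv

Analysis toolkit for the **electrosolvation force** — the long-ranged,
solvent-structure-mediated interaction that can make electrically
like-charged colloidal microspheres attract in solution and assemble into
hexagonally close-packed monolayer clusters.  The package is aimed at
researchers who infer colloidal pair potentials from microscopy-derived
radial distribution functions, and at modellers analysing interfacial
solvent structure in slab simulations.

The central model is the two-exponential pair potential between sphere
surfaces at separation *x*,

```
U(x) = A e^(−κ₁x) + B e^(−κ₂x),     κ₂ < κ₁ ≈ κ (inverse Debye length)
```

in k_BT units: a screened electrostatic repulsion (A ≥ 0) plus an
interfacial-solvation term whose amplitude B ∝ z·μ_av — the sign of the
particle charge times the excess normal dipole-moment surface density of
the interfacial solvent (D nm⁻²).  When B < 0 the potential has a single
long-ranged minimum of depth *w* at *x_min*, with the closed-form map

```
A = −w κ₂ e^(κ₁ x_min)/(κ₁−κ₂),     B = w κ₁ e^(κ₂ x_min)/(κ₁−κ₂).
```

What the package does, end to end:

- **media** — Debye screening, conductivity↔ionic-strength calibration
  (measured slope and the theoretical a = e²N_A/(6πη a_h)), osmolyte
  viscosity corrections, a 13-solvent registry.
- **potentials** — the pair law above, (w, x_min) ↔ (A, B) in both
  directions, a Derjaguin–Hamaker vdW estimate, and the z·μ_av quadrant
  rule for predicting attraction.
- **bdsim** — 2-D overdamped Brownian dynamics of polydisperse spheres in
  a periodic box (numba kernel, cell-list neighbour search, bit-exact
  seeded reproducibility).
- **structure** — g(r) with exact pair-count bookkeeping, peak analysis,
  disc rendering and centroid localization.
- **inference** — inversion of a target g(r) to (w, x_min) by simulated
  matching: coarse grid + Nelder–Mead under common random numbers.
- **interfacial** — excess interfacial dipole density μ_av from slab
  frames (φ_int = −μ_av/ε₀), species-resolved profiles, geometric H-bond
  counting; extended-XYZ frame I/O.
- **doseresponse** — additive dose–response: w/w_max normalization, Hill
  fits for c½, Boltzmann surface enrichment c_s = c_b e^(−u/k_BT), and the
  ln c½ vs u affinity regression.
- **synthetic** — generators for every input class with ground-truth
  sidecars, so the whole pipeline is testable without external data.

See `docs/methods.md` for models, assumptions and numerical choices.

## Worked example: recover a known well from simulated data

```python
import numpy as np
from esolv import (SimulationConfig, WellSpec, potential_from_well,
                   gen_equilibrium_ensemble, radial_distribution,
                   infer_potential)

# ground truth: a -5 kBT well at 0.5 um surface separation
truth = potential_from_well(WellSpec(w=-5.0, x_min=0.5, kappa1=10.0))

cfg = SimulationConfig(box_length_um=100.0, number_density_per_um2=0.008,
                       radius_mean_um=2.41, n_steps=200_000,
                       sample_interval=1000, seed=11)
frames, _ = gen_equilibrium_ensemble(truth, cfg)
g = radial_distribution(frames, r_max_um=15.0, bin_width_um=0.1)

res = infer_potential(g, cfg, kappa1=10.0,
                      w_grid=-np.arange(1.0, 8.5, 1.0), x_halfwidth_um=0.2)
print(f"w = {res.w_kBT:.2f} kBT at x_min = {res.x_min_um:.3f} um "
      f"({res.n_evaluations} BD evaluations)")
```

Output:

```
w = -4.66 kBT at x_min = 0.499 um (60 BD evaluations)
```

The generating depth was −5 k_BT at x_min = 0.5 μm: the recovered depth is
within the ±1.5 k_BT convention used when reporting well depths, and the
minimum location is recovered to well under one 0.1 μm bin.  The 80
particles cluster into hcp patches whose g(r) shows a first peak at
2R + x_min = 5.32 μm; matching that structure by repeated BD simulation is
what pins (w, x_min).

A command-line entry point mirrors the library:

```
esolv media debye --epsilon 78.4 --ionic-strength-mM 0.1 --temp 298
esolv potential build --w -5 --xmin 0.5 --kappa1 10 --table u.csv
esolv simulate --config run.yaml --potential pot.json --out traj.h5
esolv rdf --traj traj.h5 --rmax 25 --bin 0.1 --out gr.csv
esolv infer --gr gr.csv --config run.yaml --kappa1 10 --out fit.json
esolv dipole --frames slab.exyz --species water --l 1.5 --out mu.json
esolv dose fit --in tmg.csv --out fit.json
```

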