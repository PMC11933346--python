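import numpy as np
import pytest

from esolv.bdsim import Ensemble, SimulationConfig, initialize_random
from esolv.potentials import WellSpec, potential_from_well


@pytest.fixture(scope="session")
def standard_well():
    """The reference attractive potential: w = -5 kBT at x_min = 0.5 um."""
    return potential_from_well(WellSpec(w=-5.0, x_min=0.5, kappa1=10.0))


@pytest.fixture
def small_config():
    """A small, fast BD configuration (N ~= 29 in a 60 um box)."""
    return SimulationConfig(box_length_um=60.0, number_density_per_um2=0.008,
                            radius_mean_um=2.41, n_steps=30_000,
                            sample_interval=500, seed=42)


@pytest.fixture
def pair_ensemble():
    """Two particles at the standard-well minimum separation."""
    r = 2 * 2.41 + 0.5
    return Ensemble(positions=[[20.0, 20.0], [20.0 + r, 20.0]],
                    radii=[2.41, 2.41], box_length_um=60.0)
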