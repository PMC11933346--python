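"""Ground-truth generators: lattice geometry, planted counts, contracts."""

import numpy as np
import pytest

from esolv.potentials import WellSpec, potential_from_well
from esolv.bdsim import SimulationConfig
from esolv.structure import first_peak, radial_distribution
from esolv.synthetic import (
    DoseSpec, ProfileSpec, gen_dose_series, gen_equilibrium_ensemble,
    gen_hbond_config, gen_hcp_cluster, gen_ideal_gas, gen_separated,
)


class TestIdealGas:
    def test_empty(self):
        ens, truth = gen_ideal_gas(0, 50.0, seed=0)
        assert len(ens) == 0 and truth["n"] == 0

    def test_seeded_reproducibility(self):
        a, _ = gen_ideal_gas(100, 50.0, seed=1)
        b, _ = gen_ideal_gas(100, 50.0, seed=1)
        assert np.array_equal(a.positions, b.positions)


class TestHcpCluster:
    @pytest.mark.parametrize("shells,expected", [(0, 1), (1, 7), (2, 19),
                                                 (5, 91)])
    def test_centred_hexagonal_counts(self, shells, expected):
        ens, truth = gen_hcp_cluster(shells, 0.5, 2.41, 200.0)
        assert len(ens) == expected
        assert truth["n_particles"] == expected

    def test_nearest_neighbour_spacing_exact(self):
        ens, truth = gen_hcp_cluster(3, 0.5, 2.41, 100.0)
        d = ens.positions[:, None, :] - ens.positions[None, :, :]
        r = np.sqrt((d ** 2).sum(-1))
        np.fill_diagonal(r, np.inf)
        assert r.min(axis=1) == pytest.approx(truth["spacing_um"], rel=1e-9)

    def test_interior_coordination_six(self):
        ens, truth = gen_hcp_cluster(3, 0.5, 2.41, 100.0)
        centre = np.array([50.0, 50.0])  # the seed particle
        d = np.sqrt(((ens.positions - centre) ** 2).sum(1))
        neighbours = np.sum(np.abs(d - truth["spacing_um"]) < 1e-9)
        assert neighbours == 6

    def test_overflowing_box_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            gen_hcp_cluster(5, 0.5, 2.41, 30.0)


class TestEquilibriumEnsemble:
    def test_attractive_run_peaks_at_constructed_minimum(self, standard_well):
        cfg = SimulationConfig(box_length_um=60.0,
                               number_density_per_um2=0.008,
                               radius_mean_um=2.41, n_steps=100_000,
                               sample_interval=1000, seed=12)
        frames, truth = gen_equilibrium_ensemble(standard_well, cfg)
        g = radial_distribution(frames, r_max_um=15.0, bin_width_um=0.1)
        assert first_peak(g) == pytest.approx(2 * 2.41 + 0.5, abs=0.1)
        assert truth["A_kBT"] == standard_well.A

    def test_null_potential_gives_ideal_gas(self):
        from esolv.potentials import NULL_POTENTIAL
        cfg = SimulationConfig(box_length_um=100.0,
                               number_density_per_um2=0.05,
                               radius_mean_um=0.5, diffusion_um2_s=1.0,
                               n_steps=5000, sample_interval=500, seed=13)
        frames, _ = gen_equilibrium_ensemble(NULL_POTENTIAL, cfg)
        g = radial_distribution(frames, r_max_um=25.0, bin_width_um=0.5)
        assert g.g[g.r_centers_um > 2].mean() == pytest.approx(1.0, abs=0.05)


class TestCapacitorFrames:
    def test_bad_fractions_rejected(self):
        spec = ProfileSpec(species_mix={"a": (0.5, 1.0), "b": (0.4, 0.0)})
        with pytest.raises(ValueError, match="sum to 1"):
            gen_capacitor_frames_checked(spec)

    def test_overdriven_excess_rejected(self):
        from esolv.synthetic import gen_capacitor_frames
        spec = ProfileSpec(excess_mu_D_nm2=50.0, n_frames=1)
        with pytest.raises(ValueError, match="molecular magnitude"):
            gen_capacitor_frames(spec, seed=0)

    def test_truth_sidecar_complete(self):
        from esolv.synthetic import gen_capacitor_frames
        spec = ProfileSpec(excess_mu_D_nm2=0.85, n_frames=2)
        _, truth = gen_capacitor_frames(spec, seed=0)
        for key in ("excess_mu_D_nm2", "z_int_nm", "l_nm", "seed",
                    "bulk_density_per_nm3", "species_excess"):
            assert key in truth

    def test_seeded_reproducibility(self):
        from esolv.synthetic import gen_capacitor_frames
        spec = ProfileSpec(excess_mu_D_nm2=0.3, n_frames=1)
        a, _ = gen_capacitor_frames(spec, seed=4)
        b, _ = gen_capacitor_frames(spec, seed=4)
        np.testing.assert_array_equal(a[0].dipoles_D, b[0].dipoles_D)


def gen_capacitor_frames_checked(spec):
    from esolv.synthetic import gen_capacitor_frames
    return gen_capacitor_frames(spec, seed=0)


class TestHbondConfig:
    def test_planted_counts(self):
        from esolv.interfacial import hbond_count
        for n_bonds, n_decoys in ((0, 10), (5, 20), (12, 0)):
            frame, truth = gen_hbond_config(n_bonds, n_decoys, seed=2)
            assert hbond_count(frame)[0] == n_bonds

    def test_boundary_decoys_rejected_individually(self):
        """Distance decoys sit at 3.05 A (angle fine); angle decoys at 140
        degrees (distance fine) — each violates exactly one criterion."""
        from esolv.interfacial import hbond_count
        frame, _ = gen_hbond_config(0, 8, seed=1)
        assert hbond_count(frame)[0] == 0
        # relaxing one criterion at a time recovers the matching decoys
        count_wide, _ = hbond_count(frame, distance_nm=0.32)
        count_loose, _ = hbond_count(frame, angle_deg=130.0)
        assert count_wide == 4 and count_loose == 4


class TestDoseSeries:
    def test_half_maximal_at_c_half(self):
        spec = DoseSpec(c_half_M=0.05, hill=2.0, noise_sd=0.0, n_points=5,
                        c_range_M=(0.05 / 16, 0.05 * 16))
        s, _ = gen_dose_series(spec, seed=0)
        # the middle log-spaced point is exactly c_half
        assert s.c_b_M[2] == pytest.approx(0.05, rel=1e-9)
        assert s.w_kBT[2] == pytest.approx(0.5 * spec.w_max_kBT, rel=1e-9)

    def test_seeded_reproducibility(self):
        spec = DoseSpec(noise_sd=0.05)
        a, _ = gen_dose_series(spec, seed=9)
        b, _ = gen_dose_series(spec, seed=9)
        np.testing.assert_array_equal(a.w_kBT, b.w_kBT)

    def test_range_must_span_c_half(self):
        with pytest.raises(ValueError, match="span"):
            DoseSpec(c_half_M=0.05, c_range_M=(0.1, 10.0))


class TestSeparated:
    def test_gaps_and_margins(self):
        ens, _ = gen_separated(30, 80.0, 2.41, min_gap_um=1.0, seed=3)
        assert len(ens) == 30
        assert ens.positions.min() >= 2.41
        assert ens.positions.max() <= 80.0 - 2.41
        d = ens.positions[:, None, :] - ens.positions[None, :, :]
        r = np.sqrt((d ** 2).sum(-1))
        np.fill_diagonal(r, np.inf)
        assert r.min() >= 2 * 2.41 + 1.0
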