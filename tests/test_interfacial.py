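"""Excess interfacial dipole density, interface detection and H-bonds."""

import math

import numpy as np
import pytest

from esolv.interfacial import (
    DipoleDensityProfile, MolecularFrame, continuum_polarization,
    detect_interface, dipole_profile, hbond_count, mu_av, read_exyz,
    write_exyz,
)
from esolv.synthetic import ProfileSpec, gen_capacitor_frames, gen_hbond_config


def uniform_frame(n=4000, box=(4.0, 4.0, 6.0), muz=1.0, seed=0):
    """Molecules uniform in the box, all dipoles (0, 0, muz)."""
    rng = np.random.default_rng(seed)
    pos = rng.uniform(0, 1, size=(n, 3)) * np.array(box)
    mu = np.zeros((n, 3))
    mu[:, 2] = muz
    return MolecularFrame(species=np.array(["water"] * n, dtype=object),
                          positions_nm=pos, dipoles_D=mu, box_nm=box,
                          wall_positions_nm=(0.0, box[2]))


class TestDipoleProfile:
    def test_aligned_dipoles_give_density_times_moment(self):
        box = (4.0, 4.0, 6.0)
        n = 40_000
        rho = n / (box[0] * box[1] * box[2])
        prof = dipole_profile([uniform_frame(n=n)], bin_width_nm=0.25)
        interior = (prof.z_centers_nm > 0.5) & (prof.z_centers_nm < 5.5)
        assert prof.p[interior] == pytest.approx(rho * 1.0, rel=0.1)

    def test_isotropic_bulk_is_zero(self):
        spec = ProfileSpec(excess_mu_D_nm2=0.0, n_frames=4,
                           orientation_mode="vmf")
        frames, _ = gen_capacitor_frames(spec, seed=1)
        prof = dipole_profile(frames, bin_width_nm=0.2)
        # 3-sigma bound per bin from the molecular dipole variance
        rho = spec.bulk_density_per_nm3
        n_per_bin = rho * 16.0 * 0.2 * len(frames)
        se = math.sqrt(n_per_bin * spec.dipole_magnitude_D ** 2 / 3) / (
            16.0 * 0.2 * len(frames))
        assert np.abs(prof.p).max() < 3.5 * se

    def test_upper_side_sign_convention(self):
        # +z dipoles: along the inward normal at the lower wall, against it
        # at the upper wall
        fr = uniform_frame()
        lo = dipole_profile([fr], bin_width_nm=0.5, side="lower")
        up = dipole_profile([fr], bin_width_nm=0.5, side="upper")
        assert lo.p[2] > 0 > up.p[2]

    def test_unknown_species_rejected(self):
        with pytest.raises(ValueError, match="nosuch"):
            dipole_profile([uniform_frame()], species_filter="nosuch")


class TestDetectInterface:
    def _profile(self, p, bin_width=0.02):
        z = (np.arange(len(p)) + 0.5) * bin_width
        H = len(p) * bin_width
        return DipoleDensityProfile(z_centers_nm=z, p=np.asarray(p),
                                    bin_width_nm=bin_width, n_frames=1,
                                    side="lower", bulk_value=0.0,
                                    bulk_window_nm=(0.4 * H, 0.6 * H))

    def test_damped_oscillation_decay_length(self):
        """l lands within one bin of the analytic 5%-decay distance of the
        envelope."""
        bw = 0.02
        z = (np.arange(150) + 0.5) * bw
        decay = 0.3
        p = np.exp(-z / decay) * np.sin(2 * np.pi * z / 0.25 - 0.25)
        prof = self._profile(p, bw)
        z_int, l = detect_interface(prof, decay_tolerance=0.05)
        # independent scan for the first bulk crossing (sign change of p)
        flips = np.nonzero(np.sign(p[1:]) != np.sign(p[0]))[0]
        assert z_int == pytest.approx(z[flips[0] + 1], abs=1e-12)
        l_analytic = decay * math.log(1.0 / 0.05)  # envelope at 5% of max
        assert abs((z_int + l) - l_analytic) <= 3 * bw + 0.1 * l_analytic

    def test_flat_profile_degenerates_to_first_bin(self):
        prof = self._profile(np.zeros(100))
        z_int, l = detect_interface(prof)
        assert z_int == pytest.approx(0.01)
        assert l == pytest.approx(0.02)

    def test_never_reaching_bulk_raises(self):
        prof = self._profile(np.linspace(5.0, 1.0, 100))
        with pytest.raises(ValueError, match="larger box"):
            detect_interface(prof)


class TestMuAv:
    def test_prescribed_excess_round_trip(self):
        spec = ProfileSpec(excess_mu_D_nm2=0.85, n_frames=6)
        frames, truth = gen_capacitor_frames(spec, seed=1)
        lo = dipole_profile(frames, bin_width_nm=0.02, side="lower")
        up = dipole_profile(frames, bin_width_nm=0.02, side="upper")
        res = mu_av(lo, up, z_int_nm=truth["z_int_nm"], l_nm=truth["l_nm"])
        assert res.mu_av == pytest.approx(0.85, abs=0.02)
        assert res.phi_int_V == pytest.approx(-0.320, rel=0.005)

    def test_manual_l_override_honoured(self):
        spec = ProfileSpec(excess_mu_D_nm2=0.3, n_frames=2,
                           box_nm=(4.0, 4.0, 8.0))
        frames, truth = gen_capacitor_frames(spec, seed=2)
        lo = dipole_profile(frames, side="lower")
        up = dipole_profile(frames, side="upper")
        res = mu_av(lo, up, z_int_nm=0.0, l_nm=1.5)
        assert res.l_nm == 1.5

    def test_side_difference_uncertainty(self):
        spec = ProfileSpec(excess_mu_D_nm2=0.30, excess_mu_upper_D_nm2=0.26,
                           n_frames=4)
        frames, truth = gen_capacitor_frames(spec, seed=5)
        lo = dipole_profile(frames, side="lower")
        up = dipole_profile(frames, side="upper")
        res = mu_av(lo, up, z_int_nm=0.0, l_nm=truth["l_nm"])
        assert res.mu_av == pytest.approx(0.28, abs=0.01)
        assert res.uncertainty == pytest.approx(0.02, abs=0.005)

    def test_mismatched_binning_rejected(self):
        spec = ProfileSpec(n_frames=1)
        frames, truth = gen_capacitor_frames(spec, seed=0)
        lo = dipole_profile(frames, bin_width_nm=0.02, side="lower")
        up = dipole_profile(frames, bin_width_nm=0.04, side="upper")
        with pytest.raises(ValueError, match="binning"):
            mu_av(lo, up, z_int_nm=0.0, l_nm=truth["l_nm"])

    def test_interface_reaching_bulk_window_rejected(self):
        spec = ProfileSpec(n_frames=1)
        frames, truth = gen_capacitor_frames(spec, seed=0)
        lo = dipole_profile(frames, side="lower")
        up = dipole_profile(frames, side="upper")
        with pytest.raises(ValueError, match="bulk window"):
            mu_av(lo, up, z_int_nm=0.0, l_nm=3.0)

    def test_linearity_in_frames(self):
        """mu_av of concatenated frame sets equals the frame-count-weighted
        mean of the separate results."""
        spec = ProfileSpec(excess_mu_D_nm2=0.5, n_frames=2,
                           orientation_mode="vmf")
        fa, truth = gen_capacitor_frames(spec, seed=7)
        fb, _ = gen_capacitor_frames(spec, seed=8)

        def mu_of(frames):
            lo = dipole_profile(frames, side="lower")
            up = dipole_profile(frames, side="upper")
            return mu_av(lo, up, 0.0, truth["l_nm"]).mu_av

        combined = mu_of(fa + fb)
        assert combined == pytest.approx(
            (len(fa) * mu_of(fa) + len(fb) * mu_of(fb)) / (len(fa) + len(fb)),
            rel=1e-9)

    def test_mirror_invariance(self):
        """Reflecting every frame through the box midplane leaves mu_av
        unchanged (both-sides averaging with the normal flip)."""
        spec = ProfileSpec(excess_mu_D_nm2=0.4, n_frames=2)
        frames, truth = gen_capacitor_frames(spec, seed=9)
        mirrored = []
        for fr in frames:
            pos = fr.positions_nm.copy()
            pos[:, 2] = fr.box_nm[2] - pos[:, 2]
            mu = fr.dipoles_D.copy()
            mu[:, 2] = -mu[:, 2]
            mirrored.append(MolecularFrame(
                species=fr.species, positions_nm=pos, dipoles_D=mu,
                box_nm=fr.box_nm, wall_positions_nm=fr.wall_positions_nm))

        def mu_of(fs):
            lo = dipole_profile(fs, side="lower")
            up = dipole_profile(fs, side="upper")
            return mu_av(lo, up, 0.0, truth["l_nm"]).mu_av

        assert mu_of(mirrored) == pytest.approx(mu_of(frames), rel=1e-9)

    def test_species_decomposition_identity(self):
        mix = {"water": (0.9, 2.0), "zwitterion": (0.1, -1.9)}
        spec = ProfileSpec(excess_mu_D_nm2=0.1, species_mix=mix, n_frames=3,
                           dipole_magnitude_D=4.0)
        frames, truth = gen_capacitor_frames(spec, seed=6)

        def mu_of(species):
            lo = dipole_profile(frames, species_filter=species, side="lower")
            up = dipole_profile(frames, species_filter=species, side="upper")
            return mu_av(lo, up, 0.0, truth["l_nm"]).mu_av

        total, water, zwit = mu_of("all"), mu_of("water"), mu_of("zwitterion")
        assert total == pytest.approx(water + zwit, abs=1e-9)
        assert water == pytest.approx(2.0, abs=0.05)
        assert zwit == pytest.approx(-1.9, abs=0.05)


class TestContinuumPolarization:
    def test_zero_charge(self):
        assert continuum_polarization(0.0, 71.0) == 0.0

    def test_screening_factor(self):
        assert continuum_polarization(0.1, 71.0) == pytest.approx(0.0986,
                                                                  abs=2e-4)

    def test_perfect_screening_limit(self):
        assert continuum_polarization(0.1, 1e9) == pytest.approx(0.1, rel=1e-6)

    def test_permittivity_validated(self):
        with pytest.raises(ValueError):
            continuum_polarization(0.1, 1.0)


def linear_hbond_frame(d_da=0.28, angle_deg=180.0, box=5.0):
    """Two molecules: a donor-H on one, an acceptor on the other, with the
    prescribed donor-acceptor distance and D-H...A angle."""
    donor = np.array([1.0, 1.0, 1.0])
    u = np.array([1.0, 0.0, 0.0])
    h = donor + 0.1 * u
    ang = math.radians(angle_deg)
    perp = np.array([0.0, 1.0, 0.0])
    dir_ha = -u * math.cos(ang) + perp * math.sin(ang)
    dh = donor - h
    b = 2.0 * float(np.dot(dh, -dir_ha))
    c0 = float(np.dot(dh, dh)) - d_da ** 2
    t = (-b + math.sqrt(b * b - 4 * c0)) / 2.0
    acceptor = h + t * dir_ha
    nan3 = [np.nan] * 3
    return MolecularFrame(
        species=np.array(["water", "water"], dtype=object),
        positions_nm=np.array([donor, acceptor]),
        dipoles_D=np.zeros((2, 3)), box_nm=(box, box, box),
        wall_positions_nm=(0.0, box),
        donor_nm=np.array([donor, nan3]),
        hydrogen_nm=np.array([h, nan3]),
        acceptor_nm=np.array([nan3, acceptor]))


class TestHbond:
    def test_linear_bond_counted(self):
        count, pairs = hbond_count(linear_hbond_frame(0.28, 180.0))
        assert count == 1 and pairs == [(0, 1)]

    def test_distance_criterion(self):
        assert hbond_count(linear_hbond_frame(0.32, 180.0))[0] == 0

    def test_angle_criterion(self):
        assert hbond_count(linear_hbond_frame(0.28, 140.0))[0] == 0

    def test_planted_configuration(self):
        frame, truth = gen_hbond_config(5, 20, seed=3)
        assert hbond_count(frame)[0] == truth["n_bonds"]

    def test_missing_hydrogen_reported(self):
        fr = linear_hbond_frame()
        broken = MolecularFrame(
            species=fr.species, positions_nm=fr.positions_nm,
            dipoles_D=fr.dipoles_D, box_nm=fr.box_nm,
            wall_positions_nm=fr.wall_positions_nm,
            donor_nm=fr.donor_nm, hydrogen_nm=None, acceptor_nm=fr.acceptor_nm)
        with pytest.raises(ValueError, match=r"\[0\]"):
            hbond_count(broken)

    def test_brute_force_oracle_agreement(self):
        """A 200-molecule random configuration matches the O(n^2) exhaustive
        enumeration exactly."""
        rng = np.random.default_rng(11)
        n, box = 200, 4.0
        donors = rng.uniform(0, box, size=(n, 3))
        direction = rng.standard_normal((n, 3))
        direction /= np.linalg.norm(direction, axis=1, keepdims=True)
        hydros = donors + 0.1 * direction
        acceptors = rng.uniform(0, box, size=(n, 3))
        frame = MolecularFrame(
            species=np.array(["water"] * n, dtype=object),
            positions_nm=donors, dipoles_D=np.zeros((n, 3)),
            box_nm=(box, box, box), wall_positions_nm=(0.0, box),
            donor_nm=donors, hydrogen_nm=hydros, acceptor_nm=acceptors)
        count, pairs = hbond_count(frame)

        # independent oracle: plain double loop over all ordered pairs
        def mi(v):
            return v - box * np.round(v / box)

        expected = set()
        for i in range(n):
            for j in range(n):
                if i == j:
                    continue
                if np.linalg.norm(mi(donors[i] - acceptors[j])) >= 0.3:
                    continue
                vhd = mi(donors[i] - hydros[i])
                vha = mi(acceptors[j] - hydros[i])
                cosang = np.dot(vhd, vha) / (
                    np.linalg.norm(vhd) * np.linalg.norm(vha))
                if math.degrees(math.acos(np.clip(cosang, -1, 1))) > 150.0:
                    expected.add((i, j))
        assert set(pairs) == expected
        assert count == len(expected)
        assert count > 0  # the configuration actually exercises the criterion

    def test_translation_and_wrap_invariance(self):
        frame, _ = gen_hbond_config(4, 6, seed=5)
        shift = np.array([3.3, -1.7, 9.9])
        box = np.array(frame.box_nm)
        moved = MolecularFrame(
            species=frame.species,
            positions_nm=np.mod(frame.positions_nm + shift, box),
            dipoles_D=frame.dipoles_D, box_nm=frame.box_nm,
            wall_positions_nm=frame.wall_positions_nm,
            donor_nm=frame.donor_nm + shift,
            hydrogen_nm=frame.hydrogen_nm + shift,
            acceptor_nm=frame.acceptor_nm + shift)
        assert hbond_count(moved)[0] == hbond_count(frame)[0]


class TestExyzIO:
    def test_round_trip_bit_stable(self, tmp_path):
        spec = ProfileSpec(excess_mu_D_nm2=0.85, n_frames=2)
        frames, _ = gen_capacitor_frames(spec, seed=1)
        path = str(tmp_path / "slab.exyz")
        write_exyz(frames, path)
        back = read_exyz(path)
        assert len(back) == 2
        for a, b in zip(frames, back):
            assert list(a.species) == list(b.species)
            np.testing.assert_array_equal(a.positions_nm, b.positions_nm)
            np.testing.assert_array_equal(a.dipoles_D, b.dipoles_D)
            assert a.box_nm == b.box_nm
            assert a.wall_positions_nm == b.wall_positions_nm
        # a second write of what was read is byte-identical
        path2 = str(tmp_path / "slab2.exyz")
        write_exyz(back, path2)
        assert open(path).read() == open(path2).read()
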