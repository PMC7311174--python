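"""Rigid-body geometry, steric forces, confinement, and BD stepping."""

import numpy as np
import pytest

from spindlesim import geometry
from spindlesim.geometry import (Spherocylinder, bd_step,
                                 chromatin_mt_soft_repulsion, constrain_spb,
                                 min_distance_spherocylinders,
                                 mt_confinement_force, mt_drag_coefficients,
                                 steric_energy, steric_force)
from spindlesim.params import KBT_PN_NM


def _sc(center, axis, length, diameter=25.0):
    return Spherocylinder(np.array(center, float), np.array(axis, float),
                          length, diameter)


class TestMinDistance:
    def test_parallel_offset(self):
        a = _sc([0, 0, 0], [0, 0, 1], 1000.0)
        b = _sc([100, 0, 0], [0, 0, 1], 1000.0)
        d, pa, pb = min_distance_spherocylinders(a, b)
        assert d == pytest.approx(100.0 - 25.0)

    def test_crossing_perpendicular_overlap(self):
        a = _sc([0, 0, 0], [1, 0, 0], 500.0)
        b = _sc([0, 0, 0], [0, 1, 0], 500.0)
        d, _, _ = min_distance_spherocylinders(a, b)
        assert d == pytest.approx(-25.0)

    def test_degenerate_zero_length_is_sphere(self):
        a = _sc([0, 0, 0], [0, 0, 1], 0.0, 50.0)
        b = _sc([0, 0, 80], [1, 0, 0], 0.0, 50.0)
        d, _, _ = min_distance_spherocylinders(a, b)
        assert d == pytest.approx(80.0 - 50.0)

    def test_random_skew_pairs_match_brute_force(self, rng):
        """Grid-search oracle over both segment parameters, < 0.1 nm."""
        for _ in range(25):
            c1 = rng.uniform(-300, 300, 3)
            c2 = rng.uniform(-300, 300, 3)
            u1 = rng.standard_normal(3)
            u2 = rng.standard_normal(3)
            u1 /= np.linalg.norm(u1)
            u2 /= np.linalg.norm(u2)
            L1, L2 = rng.uniform(50, 800, 2)
            a = _sc(c1, u1, L1)
            b = _sc(c2, u2, L2)
            d, _, _ = min_distance_spherocylinders(a, b)
            s = np.linspace(0, 1, 401)
            p1 = a.end_minus[None] + s[:, None] * (a.end_plus - a.end_minus)[None]
            p2 = b.end_minus[None] + s[:, None] * (b.end_plus - b.end_minus)[None]
            brute = np.min(np.linalg.norm(p1[:, None] - p2[None], axis=2)) - 25.0
            assert abs(d - brute) < 0.1


class TestStericForce:
    def test_zero_beyond_and_at_cutoff(self):
        sigma = 25.0
        cutoff_sep = (2 ** (1 / 6) - 1.0) * sigma
        assert steric_force(cutoff_sep + 1.0, 2 * sigma) == 0.0
        assert steric_force(cutoff_sep, 2 * sigma) == pytest.approx(0.0, abs=1e-9)

    def test_monotone_below_cutoff(self):
        sigma = 25.0
        seps = np.linspace(-0.4 * sigma, (2 ** (1 / 6) - 1.0) * sigma, 100)
        forces = [steric_force(s, 2 * sigma) for s in seps]
        # repulsive and strictly decreasing in separation (until the clamp)
        unclamped = [f for f in forces if f < 200.0]
        assert all(np.diff(unclamped) < 0)
        assert all(f >= 0 for f in forces)

    def test_force_is_minus_energy_gradient(self):
        sigma = 25.0
        h = 1e-5
        for sep in (0.5, 1.5, 2.5):
            f = steric_force(sep, 2 * sigma, force_clamp=1e12)
            dE = (steric_energy(sep + h, 2 * sigma)
                  - steric_energy(sep - h, 2 * sigma)) / (2 * h)
            assert f == pytest.approx(-dE, rel=1e-2)


class TestChromatinRepulsion:
    def test_no_overlap_zero(self):
        chrom = _sc([0, 0, 0], [0, 0, 1], 125.0, 75.0)
        mt = _sc([200, 0, 0], [0, 0, 1], 500.0, 25.0)
        e, f = chromatin_mt_soft_repulsion(chrom, mt, amplitude=1.0)
        assert e == 0.0
        assert np.allclose(f, 0.0)

    def test_full_overlap_finite(self):
        """Coaxial overlap costs exactly the amplitude — soft, not divergent."""
        chrom = _sc([0, 0, 0], [0, 0, 1], 125.0, 75.0)
        mt = _sc([0, 0, 0], [0, 0, 1], 125.0, 25.0)
        e, f = chromatin_mt_soft_repulsion(chrom, mt, amplitude=1.0)
        assert e == pytest.approx(1.0)
        assert np.isfinite(e)

    def test_force_matches_numerical_gradient(self, rng):
        chrom = _sc([0, 0, 0], [0, 0, 1], 125.0, 75.0)
        h = 1e-4
        for _ in range(10):
            x0 = rng.uniform(10, 45)
            mt = _sc([x0, 0, 0], [0, 0, 1], 400.0, 25.0)
            e, f = chromatin_mt_soft_repulsion(chrom, mt, amplitude=1.0)
            ep, _ = chromatin_mt_soft_repulsion(
                chrom, _sc([x0 + h, 0, 0], [0, 0, 1], 400.0, 25.0), 1.0)
            em, _ = chromatin_mt_soft_repulsion(
                chrom, _sc([x0 - h, 0, 0], [0, 0, 1], 400.0, 25.0), 1.0)
            grad = (ep - em) / (2 * h)
            assert f[0] == pytest.approx(-grad, rel=1e-2, abs=1e-9)


class TestBDStep:
    def test_zero_force_zero_temperature(self, rng):
        pos = np.array([1.0, 2.0, 3.0])
        new = bd_step(pos, np.zeros(3), 100.0, 1e-5, rng, kbt=0.0)
        assert np.allclose(new, pos)

    def test_drift_law(self, rng):
        """Mean displacement after n steps equals mu F n dt (exact at T=0)."""
        mu, dt, n = 500.0, 8.9e-6, 1000
        force = np.array([2.0, 0.0, -1.0])
        pos = np.zeros(3)
        for _ in range(n):
            pos = bd_step(pos, force, mu, dt, rng, kbt=0.0)
        assert np.allclose(pos, mu * force * n * dt, rtol=1e-10)

    def test_free_diffusion_recovers_d(self, rng):
        """Sampled MSD/6t over 1e4 replicates recovers Dt within 3 SE."""
        d_target = 4.5e-4 * 1e6  # nm^2/s, SPB translational diffusion
        mu = d_target / KBT_PN_NM
        dt, n_rep = 1e-3, 10000
        disp = np.zeros((n_rep, 3))
        nsteps = 10
        for i in range(n_rep):
            p = np.zeros(3)
            for _ in range(nsteps):
                p = bd_step(p, np.zeros(3), mu, dt, rng)
            disp[i] = p
        msd = np.mean(np.sum(disp ** 2, axis=1))
        d_est = msd / (6 * nsteps * dt)
        se = d_est * np.sqrt(2.0 / (3 * n_rep))  # chi^2 variance of MSD
        assert abs(d_est - d_target) < 3 * se

    def test_rod_orientation_renormalized(self, rng):
        pos = np.zeros(3)
        u = np.array([0.0, 0.0, 1.0])
        for _ in range(100):
            pos, u = bd_step(pos, rng.standard_normal(3), (500.0, 250.0),
                             1e-5, rng, orientation=u,
                             torque=rng.standard_normal(3) * 10,
                             mobility_rot=0.01)
        assert np.linalg.norm(u) == pytest.approx(1.0, abs=1e-12)


class TestConstrainSPB:
    def test_rigid_projection_exact(self, rng):
        R = 1375.0
        for _ in range(20):
            p = rng.uniform(-2000, 2000, 3)
            if np.linalg.norm(p) < 1:
                continue
            newp, f = constrain_spb(p, "rigid", R)
            assert np.linalg.norm(newp) == pytest.approx(R, abs=1e-9)
            assert np.allclose(f, 0.0)

    def test_soft_zero_at_preferred_radius(self):
        R = 1375.0
        p = np.array([0.0, 0.0, R])
        _, f = constrain_spb(p, "soft", R)
        assert np.allclose(f, 0.0)

    def test_soft_asymptotic_wall_force(self):
        """|F| -> 17 pN within 5% at 10x the membrane tube radius."""
        R, ftube = 1375.0, 87.7
        p = np.array([0.0, 0.0, R + 10 * ftube])
        _, f = constrain_spb(p, "soft", R, spb_wall_force=17.0,
                             tube_radius=ftube)
        assert np.linalg.norm(f) == pytest.approx(17.0, rel=0.05)
        assert f[2] < 0  # restoring inward


class TestMTConfinement:
    def test_inside_zero(self):
        assert np.allclose(
            mt_confinement_force(np.array([0, 0, 1000.0]), 1375.0, "rigid"), 0)

    def test_soft_saturates_at_mt_wall_force(self):
        p = np.array([0.0, 0.0, 1375.0 + 2000.0])
        f = mt_confinement_force(p, 1375.0, "soft", mt_wall_force=2.5)
        assert np.linalg.norm(f) == pytest.approx(2.5, rel=0.01)

    def test_rigid_force_normal_to_envelope(self, rng):
        p = rng.standard_normal(3)
        p = p / np.linalg.norm(p) * 1400.0
        f = mt_confinement_force(p, 1375.0, "rigid")
        # antiparallel to the outward surface normal at contact
        cosang = np.dot(f, -p) / (np.linalg.norm(f) * np.linalg.norm(p))
        assert cosang == pytest.approx(1.0, abs=1e-12)


class TestDrags:
    def test_rotational_drag_near_cubic(self):
        _, _, g1 = mt_drag_coefficients(500.0)
        _, _, g2 = mt_drag_coefficients(1000.0)
        assert g2 / g1 > 4.0

    def test_rotational_diffusion_decreasing_in_length(self):
        lengths = np.linspace(75.0, 3000.0, 40)
        d_theta = [KBT_PN_NM / mt_drag_coefficients(L)[2] for L in lengths]
        assert all(np.diff(d_theta) < 0)

    def test_einstein_relation_identity(self):
        for L in (75.0, 300.0, 1500.0, 3000.0):
            for g in mt_drag_coefficients(L):
                assert (KBT_PN_NM / g) * g == pytest.approx(KBT_PN_NM, rel=1e-12)
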