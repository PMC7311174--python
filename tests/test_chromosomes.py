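"""Kinetochore mechanics, attachment kinetics, error correction, and
attachment-state classification."""

import itertools

import numpy as np
import pytest

from spindlesim import chromosomes as ch
from spindlesim.chromosomes import (AttachMode, ChromosomeState, Kinetochore,
                                    af_attach_rate, af_detach_rate,
                                    af_motor_step, classify_attachment,
                                    interkinetochore_energy,
                                    interkinetochore_forces,
                                    interkinetochore_stabilization,
                                    progressive_restriction_stiffness,
                                    tip_track)
from spindlesim.params import KBT_PN_NM, AttachmentParams


class TestProgressiveRestriction:
    @pytest.mark.parametrize("n,kappa", [(0, 4.1), (1, 41.0), (2, 410.0),
                                         (3, 410.0)])
    def test_table_values(self, n, kappa):
        assert progressive_restriction_stiffness(n) == kappa

    def test_invalid_occupancy_rejected(self):
        with pytest.raises(ValueError):
            progressive_restriction_stiffness(4)

    def test_binding_rate_ratio_at_angle(self):
        """Ratio between occupancy 0 and 2 at theta=30 deg is the Boltzmann
        factor of the stiffness difference."""
        th = np.deg2rad(30.0)
        r0 = af_attach_rate(AttachMode.LATERAL, 0.0, th, 0)
        r2 = af_attach_rate(AttachMode.LATERAL, 0.0, th, 2)
        expect = np.exp(-(410.0 - 4.1) * th ** 2 / (2 * KBT_PN_NM))
        assert r2 / r0 == pytest.approx(expect, rel=1e-9)


class TestAttachRate:
    def test_reference_geometry_equals_c_times_k(self):
        r = af_attach_rate(AttachMode.LATERAL, 0.0, 0.0, 0)
        assert r == pytest.approx(0.4 * 0.03)
        r = af_attach_rate(AttachMode.END_ON, 0.0, 0.0, 0,
                           tip_state="disassembling")
        assert r == pytest.approx(40.0 * 0.03)

    def test_occupied_tip_forbidden(self):
        assert af_attach_rate(AttachMode.END_ON, 0.0, 0.0, 0,
                              tip_occupied=True) == 0.0

    def test_side_vs_tip_assembling_base_rate_ratio(self):
        p = AttachmentParams()
        assert p.k_side_s / p.k_tip_assembling_s == pytest.approx(300.0)


class TestDetachRate:
    def test_side_unloaded_amphitelic(self):
        r = af_detach_rate(AttachMode.LATERAL, 0.0, 0.0, 0, amphitelic=True)
        assert r == pytest.approx(0.03)

    def test_misaligned_destabilization_factor(self):
        r = af_detach_rate(AttachMode.LATERAL, 0.0, 0.0, 0, amphitelic=False)
        assert r == pytest.approx(0.03 * 70)
        assert r == pytest.approx(2.1)

    def test_end_on_disassembling_catch_bond(self):
        r0 = af_detach_rate(AttachMode.END_ON, 0.0, 0.0, 0, amphitelic=True,
                            tip_state="disassembling")
        r2 = af_detach_rate(AttachMode.END_ON, 2.0, 0.0, 0, amphitelic=True,
                            tip_state="disassembling")
        assert r2 / r0 == pytest.approx(np.exp(2 * -3.9 / KBT_PN_NM), rel=1e-9)
        assert r2 / r0 == pytest.approx(0.150, rel=1e-2)

    def test_catch_bond_lifetime_nondecreasing(self, rng):
        """Mean end-on lifetime on a depolymerizing MT is non-decreasing in
        load over [0, 4] pN (sampled lifetimes, 1000 per load)."""
        loads = np.linspace(0.0, 4.0, 9)
        means = []
        for F in loads:
            rate = af_detach_rate(AttachMode.END_ON, F, 0.0, 0,
                                  amphitelic=True, tip_state="disassembling")
            means.append(rng.exponential(1.0 / rate, 1000).mean())
        # non-decreasing within sampling error: compare with 3-SE slack
        for a, b in zip(means[:-1], means[1:]):
            assert b > a * (1 - 3 / np.sqrt(1000))

    def test_force_ec_mode_uses_interkinetochore_force(self):
        r0 = af_detach_rate(AttachMode.LATERAL, 0.0, 0.0, 0, amphitelic=False,
                            ec_mode="force", inter_kc_force=0.0)
        r1 = af_detach_rate(AttachMode.LATERAL, 0.0, 0.0, 0, amphitelic=False,
                            ec_mode="force", inter_kc_force=1.67)
        assert r0 == pytest.approx(0.03)  # no misaligned factor in force mode
        assert r1 / r0 == pytest.approx(0.5)


class TestInterKCStabilization:
    @pytest.mark.parametrize("force,mult", [(0.0, 1.0), (1.67, 0.5),
                                            (3.34, 0.25)])
    def test_halving_per_characteristic_force(self, force, mult):
        assert interkinetochore_stabilization(force, 1.67) == pytest.approx(mult)


class TestTipTracking:
    def test_shrinkage_always_tracks(self, rng):
        assert tip_track(-10.0, rng, f_track=0.0)

    def test_full_tracking_limit(self, rng):
        assert all(tip_track(80.0, rng, f_track=1.0) for _ in range(50))

    def test_zero_tracking_limit(self, rng):
        assert not any(tip_track(8.0, rng, f_track=0.0) for _ in range(50))


class TestAFMotor:
    def test_unloaded_mean_drift_50nm_per_s(self, rng):
        n = 4000
        final = np.array([af_motor_step(0.0, 0.0, 1.0, rng) for _ in range(n)])
        se = final.std() / np.sqrt(n)
        assert abs(final.mean() - 50.0) < 3 * se

    def test_stall_no_mean_drift(self, rng):
        n = 4000
        final = np.array([af_motor_step(0.0, 5.0, 1.0, rng) for _ in range(n)])
        se = final.std() / np.sqrt(n)
        assert abs(final.mean()) < 3 * se


def _oracle(a_poles, b_poles):
    """Independent brute-force statement of the classification rules."""
    a, b = set(a_poles), set(b_poles)
    if len(a) == 2 or len(b) == 2:
        return ChromosomeState.MEROTELIC
    if len(a) == 0 and len(b) == 0:
        return ChromosomeState.LOST
    if len(a) == 0 or len(b) == 0:
        return ChromosomeState.MONOTELIC
    return (ChromosomeState.SYNTELIC if a == b
            else ChromosomeState.AMPHITELIC)


class TestClassification:
    def test_paper_examples(self):
        assert classify_attachment(["A"], ["B"]) == ChromosomeState.AMPHITELIC
        assert classify_attachment(["A", "B"], ["B"]) == ChromosomeState.MEROTELIC
        assert classify_attachment([], []) == ChromosomeState.LOST
        assert classify_attachment(["A", "A"], []) == ChromosomeState.MONOTELIC
        assert classify_attachment(["A"], ["A"]) == ChromosomeState.SYNTELIC

    def test_exhaustive_enumeration_matches_oracle(self):
        """All 3-site x 2-sister x {none, pole A, pole B} patterns."""
        options = [None, "A", "B"]
        for pat_a in itertools.product(options, repeat=3):
            for pat_b in itertools.product(options, repeat=3):
                a = [p for p in pat_a if p]
                b = [p for p in pat_b if p]
                assert classify_attachment(a, b) == _oracle(a, b)

    def test_permutation_invariance(self):
        """Swapping sister labels and pole labels preserves the state."""
        options = [None, "A", "B"]
        swap = {"A": "B", "B": "A"}
        for pat_a in itertools.product(options, repeat=2):
            for pat_b in itertools.product(options, repeat=2):
                a = [p for p in pat_a if p]
                b = [p for p in pat_b if p]
                direct = classify_attachment(a, b)
                swapped = classify_attachment([swap[p] for p in b],
                                              [swap[p] for p in a])
                assert direct == swapped


def _pair(sep=100.0, tilt=0.0):
    a = Kinetochore(np.zeros(3), [-1.0, 0.0, 0.0], [0.0, 1.0, 0.0])
    n2 = np.array([np.cos(tilt), np.sin(tilt), 0.0])
    b = Kinetochore(np.array([sep, 0.0, 0.0]), n2, [0.0, 1.0, 0.0])
    return a, b


class TestInterKCForces:
    def test_rest_configuration_zero(self):
        a, b = _pair(100.0)
        f, ta, tb = interkinetochore_forces(a, b)
        assert np.allclose(f, 0.0, atol=1e-12)
        assert np.allclose(ta, 0.0, atol=1e-9)
        assert np.allclose(tb, 0.0, atol=1e-9)

    def test_hooke_tension_at_200nm(self):
        a, b = _pair(200.0)
        f, _, _ = interkinetochore_forces(a, b)
        # 39 pN/um x 0.1 um = 3.9 pN, pulling a toward b
        assert np.linalg.norm(f) == pytest.approx(3.9)
        assert f[0] > 0

    def test_torque_matches_numerical_gradient(self):
        """Rotational torque equals minus dE/dtheta to 1%."""
        h = 1e-5
        for tilt in (0.3, 0.8, 1.5):
            a, b = _pair(100.0, tilt)
            _, _, tb = interkinetochore_forces(a, b)
            ep = interkinetochore_energy(*_pair(100.0, tilt + h))
            em = interkinetochore_energy(*_pair(100.0, tilt - h))
            dE = (ep - em) / (2 * h)
            # torque component about z (the rotation axis used by tilt)
            assert tb[2] == pytest.approx(-dE, rel=1e-2)

    def test_newtons_third_law_linear(self):
        a, b = _pair(173.0)
        f, _, _ = interkinetochore_forces(a, b)
        f2, _, _ = interkinetochore_forces(b, a)
        assert np.allclose(f, -f2)

    def test_site_positions_collinear_40nm_apart(self):
        a, _ = _pair()
        sites = a.site_positions()
        assert sites.shape == (3, 3)
        assert np.linalg.norm(sites[1] - sites[0]) == pytest.approx(40.0)
        assert np.linalg.norm(sites[2] - sites[1]) == pytest.approx(40.0)
        v1 = sites[1] - sites[0]
        v2 = sites[2] - sites[1]
        assert np.allclose(np.cross(v1, v2), 0.0, atol=1e-9)
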