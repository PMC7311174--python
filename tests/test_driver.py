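"""Configuration handling, presets, initialization, and run contracts."""

import numpy as np
import pytest

from spindlesim import engine, geometry
from spindlesim.driver import initialize_state, run
from spindlesim.params import ConfigError, ModelParams, load_config, save_config
from spindlesim.presets import PRESETS, get_preset


class TestConfig:
    def test_empty_config_gives_reference_defaults(self, tmp_path):
        p = tmp_path / "empty.yaml"
        p.write_text("")
        mp = load_config(p)
        assert mp.kinesin5.number == 174
        assert mp.simulation.time_step_s == pytest.approx(8.9e-6)
        assert mp.attachment.misaligned_destabilization == 70.0

    def test_kinesin5_deletion_via_config(self, tmp_path):
        p = tmp_path / "k5.yaml"
        p.write_text("kinesin5:\n  number: 0\n")
        assert load_config(p).kinesin5.number == 0

    def test_unknown_key_rejected_by_name(self, tmp_path):
        p = tmp_path / "bad.yaml"
        p.write_text("kinesin5:\n  velocity_typo: 3\n")
        with pytest.raises(ConfigError, match="velocity_typo"):
            load_config(p)

    def test_unknown_section_rejected(self, tmp_path):
        p = tmp_path / "bad.yaml"
        p.write_text("kinesin99:\n  number: 0\n")
        with pytest.raises(ConfigError, match="kinesin99"):
            load_config(p)

    def test_negative_time_step_rejected(self, tmp_path):
        p = tmp_path / "bad.yaml"
        p.write_text("simulation:\n  time_step_s: -1.0e-6\n")
        with pytest.raises(ConfigError, match="time_step_s"):
            load_config(p)

    def test_round_trip(self, tmp_path):
        mp = get_preset("weak_rescue")
        f = tmp_path / "cfg.yaml"
        save_config(mp, f)
        back = load_config(f)
        assert back.to_dict() == mp.to_dict()

    def test_pack_order_stable(self):
        from spindlesim.params import PARAM_INDEX, PARAM_NAMES
        v = ModelParams().pack()
        assert v.shape == (len(PARAM_NAMES),)
        assert v[PARAM_INDEX["radius"]] == pytest.approx(1375.0)
        assert v[PARAM_INDEX["vg0"]] == pytest.approx(4.1 * 1000 / 60)


class TestPresets:
    def test_all_presets_valid(self):
        for name in PRESETS:
            get_preset(name).pack()

    def test_reference_untouched(self):
        assert get_preset("reference").to_dict() == ModelParams().to_dict()

    def test_unknown_preset(self):
        with pytest.raises(ConfigError):
            get_preset("nope")

    def test_force_ec_block(self):
        mp = get_preset("force_ec")
        assert mp.error_correction.mode == "force"
        assert mp.chromosome.inter_kc_rot_pn_nm == 925.0
        assert mp.kinesin5.number == 200


@pytest.fixture(scope="module")
def state():
    return initialize_state(ModelParams(), np.random.default_rng(3))


class TestInitialState:

    def test_spb_bridge_separation(self, state):
        assert np.linalg.norm(state.spb_pos[1] - state.spb_pos[0]) \
            == pytest.approx(75.0)

    def test_spbs_on_envelope(self, state):
        for p in state.spb_pos:
            assert np.linalg.norm(p) == pytest.approx(1375.0)

    def test_mt_counts_and_lengths(self, state):
        assert state.n_mts == 28
        assert (state.mt_len == 75.0).all()
        assert (state.mt_state == 1).all()
        assert np.bincount(state.mt_spb).tolist() == [14, 14]

    def test_three_chromosomes_at_rest_separation(self, state):
        assert state.kc_pos.shape == (6, 3)
        for c in range(3):
            sep = np.linalg.norm(state.kc_pos[2 * c + 1] - state.kc_pos[2 * c])
            assert sep == pytest.approx(100.0)

    def test_everything_unbound(self, state):
        assert (state.lk_state == 0).all()
        assert (state.af_mode == 0).all()

    def test_no_initial_steric_overlaps(self, state):
        """All pairwise MT-kinetochore and MT-chromatin separations >= 0."""
        mts = [geometry.Spherocylinder(state.mt_center[i], state.mt_axis[i],
                                       state.mt_len[i], 25.0)
               for i in range(state.n_mts)]
        for k in range(6):
            plate = geometry.Spherocylinder(state.kc_pos[k], state.kc_t[k],
                                            100.0, 50.0)
            for m in mts:
                d, _, _ = geometry.min_distance_spherocylinders(plate, m)
                assert d >= 0.0
        for c in range(3):
            center = 0.5 * (state.kc_pos[2 * c] + state.kc_pos[2 * c + 1])
            axis = state.kc_pos[2 * c + 1] - state.kc_pos[2 * c]
            chrom = geometry.Spherocylinder(center, axis, 125.0, 75.0)
            for m in mts:
                d, _, _ = geometry.min_distance_spherocylinders(chrom, m)
                assert d >= 0.0


def _short(preset="reference", duration=0.2, seed=1, **overrides):
    p = get_preset(preset)
    p.simulation.duration_s = duration
    p.simulation.sample_interval_s = 0.05
    for key, v in overrides.items():
        blk, k = key.split("__")
        setattr(getattr(p, blk), k, v)
    return run(p, seed)


class TestRunContracts:
    def test_same_seed_bitwise_identical(self):
        t1 = _short(seed=11)
        t2 = _short(seed=11)
        assert np.array_equal(t1.spindle_length_nm, t2.spindle_length_nm)
        assert np.array_equal(t1.kc_positions_nm, t2.kc_positions_nm)
        assert np.array_equal(t1.bound_counts, t2.bound_counts)

    def test_different_seeds_differ(self):
        t1 = _short(seed=11)
        t2 = _short(seed=12)
        assert not np.array_equal(t1.kc_positions_nm, t2.kc_positions_nm)

    def test_copy_number_conservation(self):
        t = _short(duration=0.5)
        totals = t.bound_counts.sum(axis=2)
        assert (totals[:, 0] == 174).all()
        assert (totals[:, 1] == 230).all()
        assert (totals[:, 2] == 657).all()

    def test_rigid_mode_spb_radius_exact(self):
        t = _short(duration=0.5)
        r = np.linalg.norm(t.spb_positions_nm, axis=2)
        assert np.max(np.abs(r - 1375.0)) < 1e-6

    def test_sampling_stride_does_not_alter_dynamics(self):
        p1 = get_preset("reference")
        p1.simulation.duration_s = 0.2
        p1.simulation.sample_interval_s = 0.05
        t1 = run(p1, 7)
        p2 = get_preset("reference")
        p2.simulation.duration_s = 0.2
        p2.simulation.sample_interval_s = 0.1
        t2 = run(p2, 7)
        # shared sample times agree exactly
        common1 = np.isin(t1.times_s, t2.times_s)
        assert np.array_equal(t1.spindle_length_nm[common1],
                              t2.spindle_length_nm)

    def test_soft_envelope_runs_and_spb_moves_radially(self):
        t = _short(preset="soft_envelope", duration=0.5)
        r = np.linalg.norm(t.spb_positions_nm, axis=2)
        assert np.isfinite(r).all()
        # free to leave the sphere but confined near it
        assert np.max(np.abs(r - 1375.0)) > 1e-9
        assert np.max(np.abs(r - 1375.0)) < 500.0

    def test_trajectory_hdf5_round_trip(self, tmp_path):
        """Stored trajectories reload bit-identically, config included."""
        t1 = _short(duration=0.2, seed=9)
        f = tmp_path / "traj.h5"
        t1.save_hdf5(f)
        t2 = __import__("spindlesim").Trajectory.load_hdf5(f)
        assert np.array_equal(t1.spindle_length_nm, t2.spindle_length_nm)
        assert np.array_equal(t1.af_mt, t2.af_mt)
        assert t2.params.to_dict() == t1.params.to_dict()
        assert t2.seed == t1.seed

    def test_no_two_end_on_attachments_share_a_tip(self):
        """Global invariant: at most one end-on attachment per MT plus end."""
        t = _short(duration=2.0, seed=5)
        endon = t.af_mode == engine.AF_ENDON
        for s in range(t.af_mode.shape[0]):
            tips = t.af_mt[s][endon[s]]
            assert len(tips) == len(set(tips.tolist()))
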