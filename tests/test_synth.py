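"""Generator structure: determinism, behavioral realism, latent composition,
forward-model identifiability, session round-trips."""

import dataclasses

import numpy as np
import pytest

from cholinepipe import behavior, photometry, session_io, synth
from cholinepipe.synth import GeneratorConfig, GroundTruth


def _short(seed=0, dur=180.0, **kw):
    return GeneratorConfig(seed=seed, session_duration=dur, **kw)


class TestDeterminism:
    def test_identical_seed_identical_session(self):
        a = synth.simulate_session(_short(seed=11))
        b = synth.simulate_session(_short(seed=11))
        assert np.array_equal(a.traj.neck_xy, b.traj.neck_xy)
        assert np.array_equal(a.truth.z_true, b.truth.z_true)
        assert a.photometry.f465.tobytes() == b.photometry.f465.tobytes()
        assert a.photometry.f405.tobytes() == b.photometry.f405.tobytes()
        for name in behavior.BEHAVIORS:
            assert np.array_equal(a.etho.flags[name], b.etho.flags[name])

    def test_different_seed_differs(self):
        a = synth.simulate_session(_short(seed=1))
        b = synth.simulate_session(_short(seed=2))
        assert not np.array_equal(a.truth.z_true, b.truth.z_true)


class TestTrajectory:
    def test_positions_in_arena_and_speed_nonnegative(self):
        traj = synth.simulate_trajectory(_short(seed=4))
        assert traj.neck_xy.min() >= -1.0 and traj.neck_xy.max() <= 41.0
        assert traj.nose_xy.min() >= 0.0 and traj.nose_xy.max() <= 40.0
        assert (traj.speed >= 0).all()

    def test_locomotion_faster_than_rest(self):
        cfg = _short(seed=5, dur=300.0)
        traj = synth.simulate_trajectory(cfg)
        etho = synth.simulate_ethogram(cfg, traj)
        loco = etho.flags["locomotion"]
        assert traj.speed[loco].mean() > 2 * traj.speed[~loco].mean()

    def test_exploratory_drive_decays(self):
        """Early-session speed exceeds late-session speed (Monte-Carlo over seeds)."""
        wins = 0
        for seed in range(10):
            traj = synth.simulate_trajectory(_short(seed=seed, dur=300.0))
            n = int(60 * traj.rate)
            wins += traj.speed[:n].mean() > traj.speed[-n:].mean()
        assert wins >= 8

    def test_zero_locomotion_weight_gives_low_speed(self):
        cfg = _short(
            seed=0,
            state_weights={"locomotion": 0.0, "grooming": 0.3, "rearing": 0.2,
                           "background": 0.5, "object": 0.0},
            speed_decay_amp=0.0,
        )
        traj = synth.simulate_trajectory(cfg)
        assert traj.speed.mean() < 3.0


class TestEthogram:
    def test_exclusivity_and_explore_overlap_rules(self):
        cfg = _short(seed=6, dur=300.0)
        traj = synth.simulate_trajectory(cfg)
        etho = synth.simulate_ethogram(cfg, traj)
        excl = (
            etho.flags["locomotion"].astype(int)
            + etho.flags["grooming"].astype(int)
            + etho.flags["rearing"].astype(int)
        )
        assert excl.max() <= 1
        assert etho.flags["grooming"].sum() > 0
        explore = etho.explore_any()
        assert not (explore & etho.flags["grooming"]).any()

    def test_exploration_requires_nose_near_object(self):
        cfg = _short(seed=7, dur=300.0)
        traj = synth.simulate_trajectory(cfg)
        etho = synth.simulate_ethogram(cfg, traj)
        for key, flag in (("stat", "explore_stat"), ("nonstat", "explore_nonstat")):
            frames = etho.flags[flag]
            if frames.any():
                d = np.linalg.norm(
                    traj.nose_xy[frames] - np.asarray(cfg.objects[key]), axis=1
                )
                assert d.max() <= cfg.object_radius + 1e-9

    def test_symmetric_preference_gives_zero_mean_di(self):
        dis = []
        for seed in range(50):
            cfg = _short(seed=seed, dur=300.0, phase="test", test_preference=1.0)
            traj = synth.simulate_trajectory(cfg)
            etho = synth.simulate_ethogram(cfg, traj)
            try:
                dis.append(behavior.window_di(etho, 0.0, 300.0).di)
            except ValueError:
                continue
        assert len(dis) > 40
        assert abs(np.mean(dis)) < 0.1

    def test_test_phase_preference_biases_early_exploration(self):
        early_di = []
        for seed in range(12):
            cfg = _short(seed=seed, dur=300.0, phase="test", test_preference=3.0)
            traj = synth.simulate_trajectory(cfg)
            etho = synth.simulate_ethogram(cfg, traj)
            try:
                early_di.append(behavior.window_di(etho, 0.0, 180.0).di)
            except ValueError:
                continue
        assert np.mean(early_di) > 0.15

    def test_long_dwell_yields_bouts_of_every_behavior(self):
        for seed in range(20):
            cfg = GeneratorConfig(
                seed=seed,
                session_duration=900.0,
                dwell_params={"locomotion": 10.0, "grooming": 10.0, "rearing": 10.0,
                              "background": 10.0, "object": 10.0},
            )
            traj = synth.simulate_trajectory(cfg)
            etho = synth.simulate_ethogram(cfg, traj)
            for name in ("locomotion", "grooming", "rearing"):
                runs = behavior.extract_bouts(
                    etho.flags[name], etho.t, name, min_dur=2.0, isolation=0.0
                )
                assert len(runs) >= 1, f"seed {seed}: no {name} bout of >= 2 s"

    def test_default_session_has_filtered_bouts_per_behavior(self):
        sess = synth.simulate_session(GeneratorConfig(seed=1))
        for name in behavior.BEHAVIORS[:-1]:
            bouts = behavior.extract_bouts(sess.etho.flags[name], sess.etho.t, name)
            assert len(bouts) >= 5, f"behavior {name}: {len(bouts)} filtered bouts"


class TestGroundTruth:
    def test_null_generator(self):
        cfg = _short(beta_speed=0.0, beta_groom=0.0, beta_rear=0.0, novelty_amp=0.0,
                     recency_amp=0.0, noise_sd=0.0)
        traj = synth.simulate_trajectory(cfg)
        etho = synth.simulate_ethogram(cfg, traj)
        truth = synth.simulate_ground_truth(cfg, traj, etho)
        assert np.allclose(truth.z_true, 0.0)

    def test_recency_exponential_identity(self):
        cfg = _short(beta_speed=0.0, beta_groom=0.0, beta_rear=0.0, novelty_amp=0.0,
                     recency_amp=2.0, recency_tau=28.0, noise_sd=0.0)
        traj = synth.simulate_trajectory(cfg)
        etho = synth.simulate_ethogram(cfg, traj)
        truth = synth.simulate_ground_truth(cfg, traj, etho)
        i_tau = int(round(28.0 * cfg.video_rate))
        assert truth.z_true[i_tau] / truth.z_true[0] == pytest.approx(np.exp(-1), rel=1e-3)

    def test_components_sum_exactly(self):
        sess = synth.simulate_session(_short(seed=9))
        total = sum(sess.truth.components.values())
        assert np.allclose(total, sess.truth.z_true, atol=1e-12)
        with pytest.raises(ValueError, match="sum"):
            GroundTruth(
                t=np.arange(3.0), rate=1.0, z_true=np.ones(3),
                components={"a": np.zeros(3)},
            )

    def test_speed_component_dominates_off_bout_frames(self):
        """Noise off: z tracks log2 speed wherever no behavior term is active."""
        for seed in range(3):
            cfg = GeneratorConfig(seed=seed, noise_sd=0.0)
            traj = synth.simulate_trajectory(cfg)
            etho = synth.simulate_ethogram(cfg, traj)
            truth = synth.simulate_ground_truth(cfg, traj, etho)
            quiet = ~(
                etho.flags["grooming"] | etho.flags["rearing"] | etho.explore_any()
            )
            late = truth.t > 120.0
            sel = quiet & late
            l2s = np.log2(np.maximum(traj.speed, cfg.speed_floor))
            assert np.corrcoef(truth.z_true[sel], l2s[sel])[0, 1] > 0.95


class TestRenderPhotometry:
    def test_artifact_only_channels_proportional(self):
        cfg = _short(beta_speed=0.0, beta_groom=0.0, beta_rear=0.0, novelty_amp=0.0,
                     recency_amp=0.0, noise_sd=0.0, motion_amp=0.0)
        traj = synth.simulate_trajectory(cfg)
        etho = synth.simulate_ethogram(cfg, traj)
        truth = synth.simulate_ground_truth(cfg, traj, etho)
        phot = synth.render_photometry(cfg, truth)
        ratio = phot.f465 / phot.f405
        assert np.allclose(ratio, ratio[0], atol=1e-9)

    def test_constant_bleach_recovers_z_proportionally(self):
        bp = synth.BleachParams(amp_fast=0.0, amp_slow=0.0)
        cfg = _short(seed=2, noise_sd=0.5, motion_amp=0.0, bleach_params=bp)
        traj = synth.simulate_trajectory(cfg)
        etho = synth.simulate_ethogram(cfg, traj)
        truth = synth.simulate_ground_truth(cfg, traj, etho)
        phot = synth.render_photometry(cfg, truth)
        dff_direct = (phot.f465 - bp.base) / bp.base
        z_up = np.interp(phot.t, truth.t, truth.z_true)
        assert np.corrcoef(dff_direct, z_up)[0, 1] > 0.999999

    def test_excessive_gain_raises(self):
        bp = synth.BleachParams(gain=5.0)
        cfg = _short(seed=3, recency_amp=10.0, bleach_params=bp)
        traj = synth.simulate_trajectory(cfg)
        etho = synth.simulate_ethogram(cfg, traj)
        truth = synth.simulate_ground_truth(cfg, traj, etho)
        with pytest.raises(ValueError, match="nonpositive"):
            synth.render_photometry(cfg, truth)

    def test_end_to_end_recovery_at_defaults(self):
        """Full default session: corrected ΔF/F correlates > 0.9 with the latent."""
        sess = synth.simulate_session(GeneratorConfig(seed=8))
        series = photometry.preprocess(sess.photometry)
        n = min(series.values.size, sess.truth.z_true.size)
        assert np.corrcoef(series.values[:n], sess.truth.z_true[:n])[0, 1] > 0.9


class TestSessionRoundTrip:
    def test_write_read_equality(self, tmp_path):
        sess = synth.simulate_session(_short(seed=13, dur=90.0))
        directory = synth.write_session(sess, tmp_path / "s0")
        loaded = session_io.read_session(directory)
        assert np.array_equal(loaded.photometry.f465, sess.photometry.f465)
        assert np.array_equal(loaded.photometry.f405, sess.photometry.f405)
        assert loaded.photometry.meta == sess.photometry.meta
        assert np.array_equal(loaded.traj.neck_xy, sess.traj.neck_xy)
        for name in behavior.BEHAVIORS:
            assert np.array_equal(loaded.etho.flags[name], sess.etho.flags[name])
        assert np.array_equal(loaded.truth.z_true, sess.truth.z_true)
        assert loaded.config["seed"] == 13

    def test_missing_parent_directory_raises(self, tmp_path):
        sess = synth.simulate_session(_short(seed=13, dur=90.0))
        with pytest.raises(FileNotFoundError):
            synth.write_session(sess, tmp_path / "no" / "such" / "dir")

    def test_schema_version_validated(self, tmp_path):
        import h5py

        sess = synth.simulate_session(_short(seed=13, dur=90.0))
        directory = synth.write_session(sess, tmp_path / "s1")
        with h5py.File(directory / "photometry.h5", "a") as f:
            f.attrs["schema_version"] = 999
        with pytest.raises(ValueError, match="schema_version"):
            session_io.read_session(directory)

    def test_config_validation(self):
        with pytest.raises(ValueError, match="dwell"):
            GeneratorConfig(dwell_params={"locomotion": 1.0, "grooming": 6.0,
                                          "rearing": 4.0, "background": 6.0, "object": 6.0})
        with pytest.raises(ValueError, match="outside arena"):
            GeneratorConfig(object_centers={"sample": {"stat": (50.0, 10.0),
                                                       "nonstat": (30.0, 10.0)},
                                            "test": {"stat": (10.0, 10.0),
                                                     "nonstat": (30.0, 30.0)}})
        with pytest.raises(ValueError, match="session_duration"):
            GeneratorConfig(session_duration=10.0)
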