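"""Simulator self-consistency, determinism and protocol properties."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from armtrack import synthetic as syn
from armtrack.imu import ImuRecording


class TestGenerateSession:
    def test_same_seed_is_byte_identical(self):
        script = syn.sports_script(2, 2, seed=9)
        r1, t1 = syn.generate_session(script)
        r2, t2 = syn.generate_session(script)
        for name in ("t", "accel", "gyro", "mag"):
            np.testing.assert_array_equal(getattr(r1, name), getattr(r2, name))
        assert [e.peak_rate_time for e in t1.events] == [
            e.peak_rate_time for e in t2.events
        ]

    def test_rest_only_zero_noise_is_static(self):
        script = syn.SessionScript(blocks=(("rest", 3),), seed=0)
        rec, truth = syn.generate_session(script, syn.NoiseConfig.zero())
        assert np.max(np.abs(rec.gyro)) < 1e-9
        assert np.max(np.abs(truth.theta - truth.theta[0])) < 1e-9
        # hanging arm: accel is the unit gravity direction near +x
        np.testing.assert_allclose(np.linalg.norm(rec.accel, axis=1), 1.0, atol=1e-9)
        assert rec.accel[0, 0] == pytest.approx(np.cos(np.radians(8.0)), abs=1e-6)

    def test_static_accel_magnitude_one_g_with_noise(self):
        script = syn.SessionScript(blocks=(("rest", 5),), seed=1)
        noise = syn.NoiseConfig()
        rec, _ = syn.generate_session(script, noise)
        norms = np.linalg.norm(rec.accel, axis=1)
        assert abs(norms.mean() - 1.0) < 3 * noise.accel_noise_g

    def test_gyro_matches_differentiated_attitude(self):
        """Finite differences of the true quaternion track reproduce the
        emitted (noiseless) gyro series to < 1 deg/s RMS."""
        script = syn.exercises_only_script(seed=7, reps=2)
        rec, truth = syn.generate_session(script, syn.NoiseConfig.zero())
        q = truth.quat
        r = Rotation.from_quat(np.column_stack([q[:, 1], q[:, 2], q[:, 3], q[:, 0]]))
        central = (r[:-2].inv() * r[2:]).as_rotvec(degrees=True) * (rec.fs / 2.0)
        rms = np.sqrt(np.mean((central - truth.omega_dev[1:-1]) ** 2))
        assert rms < 1.0

    def test_ground_truth_counts_match_script(self):
        script = syn.SessionScript(
            blocks=(("baseball_throw", 3), ("flexion", 4), ("volleyball_serve", 2)),
            seed=5,
        )
        rec, truth = syn.generate_session(script)
        assert truth.sport_counts == {"Throw": 3, "Serve": 2}
        assert truth.counts["flexion"] == 4
        assert len(truth.events) == 9
        assert isinstance(rec, ImuRecording)

    def test_events_separated_by_rest_rule(self):
        rec, truth = syn.generate_session(syn.sports_script(5, 5, seed=2))
        times = [e.peak_rate_time for e in truth.sport_events()]
        assert np.all(np.diff(times) > 1.0)

    def test_throw_and_serve_have_distinct_rotation_axes(self):
        rec, truth = syn.generate_session(
            syn.sports_script(3, 3, seed=8), syn.NoiseConfig.zero()
        )
        rate = np.linalg.norm(truth.omega_dev, axis=1)
        for ev in truth.sport_events():
            i = int(round(ev.peak_rate_time * rec.fs))
            axis = truth.omega_dev[i] / rate[i]
            if ev.activity == "baseball_throw":
                assert abs(axis[0]) > 0.7   # internal rotation about the arm axis
            else:
                assert abs(axis[0]) < 0.5   # elevation-plane swing

    def test_gyro_clipping_configurable(self):
        noise = syn.NoiseConfig(gyro_clip_dps=2000.0)
        rec, _ = syn.generate_session(syn.sports_script(3, 0, seed=4), noise)
        assert np.max(np.abs(rec.gyro)) <= 2000.0

    def test_unknown_template_rejected(self):
        with pytest.raises(syn.SyntheticError):
            syn.SessionScript(blocks=(("cartwheel", 2),), seed=0)

    def test_invalid_reps_rejected(self):
        with pytest.raises(syn.SyntheticError):
            syn.SessionScript(blocks=(("flexion", 0),), seed=0)

    def test_short_gaps_rejected(self):
        with pytest.raises(syn.SyntheticError):
            syn.SessionScript(blocks=(("flexion", 1),), seed=0, gap_range=(0.2, 0.5))


class TestBenchmarkSuite:
    def test_suite_sizes(self):
        suite = syn.default_benchmark_suite(seed=0)
        assert len(suite.control) == 11
        assert len(suite.randomized) == 11

    def test_control_protocol_is_fixed_order_eight_reps(self):
        suite = syn.default_benchmark_suite(seed=0)
        for script in suite.control:
            assert all(reps == 8 for _, reps in script.blocks)
            assert [n for n, _ in script.blocks] == list(syn.EXERCISES) + [
                syn.BASEBALL_THROW, syn.VOLLEYBALL_SERVE,
            ]

    def test_randomized_rep_ranges(self):
        suite = syn.default_benchmark_suite(seed=0)
        for script in suite.randomized:
            for name, reps in script.blocks:
                if name in syn.SPORTS:
                    assert 4 <= reps <= 12
                else:
                    assert 2 <= reps <= 6

    def test_subject_scales_within_band(self):
        suite = syn.default_benchmark_suite(seed=3)
        for c, r in zip(suite.control, suite.randomized):
            assert 0.85 <= c.subject_scale <= 1.15
            assert c.subject_scale == r.subject_scale  # same simulated subject

    def test_different_seeds_shuffle_differently(self):
        a = syn.default_benchmark_suite(seed=0)
        b = syn.default_benchmark_suite(seed=1)
        orders_a = [tuple(n for n, _ in s.blocks) for s in a.randomized]
        orders_b = [tuple(n for n, _ in s.blocks) for s in b.randomized]
        assert orders_a != orders_b
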