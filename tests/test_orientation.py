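"""Elevation estimators and complementary-filter behaviour."""

import math

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from armtrack import synthetic as syn
from armtrack.imu import ImuSample
from armtrack.orientation import (
    FusionConfig,
    OrientationError,
    OrientationState,
    UndefinedAngleError,
    ahrs_step,
    elevation_from_accel,
    elevation_from_quats,
    elevation_from_state,
    estimate_series,
    quat_to_dcm,
)
from conftest import make_recording


class TestElevationFromAccel:
    @pytest.mark.parametrize(
        "accel, expected",
        [((1.0, 0.0, 0.0), 0.0), ((0.0, 1.0, 0.0), 90.0), ((0.5, 0.8660254, 0.0), 60.0)],
    )
    def test_known_angles(self, accel, expected):
        assert elevation_from_accel(accel) == pytest.approx(expected, abs=1e-4)

    def test_near_zero_vector_rejected(self):
        with pytest.raises(UndefinedAngleError):
            elevation_from_accel((1e-9, 0.0, 0.0))

    def test_magnitude_invariance(self):
        assert elevation_from_accel((3.0, 4.0, 0.0)) == pytest.approx(
            elevation_from_accel((0.3, 0.4, 0.0))
        )


class TestElevationFromState:
    def test_identity_dcm_is_horizontal_arm(self):
        state = OrientationState(q=(1.0, 0.0, 0.0, 0.0))
        assert elevation_from_state(state) == pytest.approx(90.0, abs=1e-9)

    def test_x_axis_at_nadir_is_zero(self):
        # rotate device x onto (0,0,-1): Ry(+90 deg)
        r = Rotation.from_euler("y", 90, degrees=True)
        x, y, z, w = r.as_quat()
        state = OrientationState(q=(w, x, y, z))
        assert elevation_from_state(state) == pytest.approx(0.0, abs=1e-9)

    def test_matches_angle_between_vectors_oracle(self):
        rots = Rotation.random(200, random_state=7)
        for r in rots:
            x, y, z, w = r.as_quat()
            state = OrientationState(q=(w, x, y, z))
            # brute-force oracle: explicit angle between R@e_x and nadir
            v = r.as_matrix() @ np.array([1.0, 0.0, 0.0])
            expected = math.degrees(
                math.atan2(np.linalg.norm(np.cross(v, [0, 0, -1])), v @ [0, 0, -1])
            )
            assert elevation_from_state(state) == pytest.approx(expected, abs=1e-9)


class TestAhrsStep:
    def test_static_input_is_a_fixed_point(self):
        # arm hanging: accel along +x, North along device +y
        cfg = FusionConfig()
        samp = ImuSample(0.0, np.array([1.0, 0.0, 0.0]),
                         np.zeros(3), np.array([0.0, 1.0, 0.0]))
        from armtrack.orientation import triad_init

        state = OrientationState(q=triad_init(samp.accel, samp.mag))
        theta0 = elevation_from_state(state)
        for _ in range(100):
            state = ahrs_step(state, samp, 0.02, cfg)
        assert elevation_from_state(state) == pytest.approx(theta0, abs=1e-6)
        assert theta0 == pytest.approx(0.0, abs=1e-6)

    def test_gyro_only_constant_rate_heading(self):
        """gain 0, gyro (0,0,90) deg/s for 1 s at 50 Hz -> 90 deg heading."""
        cfg = FusionConfig(gain=0.0)
        samp = ImuSample(0.0, np.array([0.0, 0.0, -1.0]),
                         np.array([0.0, 0.0, 90.0]), np.array([1.0, 0.0, 0.0]))
        state = OrientationState(q=(1.0, 0.0, 0.0, 0.0))
        for _ in range(50):
            state = ahrs_step(state, samp, 0.02, cfg)
        w, x, y, z = state.q
        yaw = math.degrees(2.0 * math.atan2(z, w))
        assert yaw == pytest.approx(90.0, abs=0.1)

    def test_gyro_only_matches_axis_angle_closed_form(self):
        """constant-rate integration error < 0.2 deg per 90 deg at 50 Hz."""
        rs = np.random.default_rng(5)
        axis = rs.normal(size=3)
        axis /= np.linalg.norm(axis)
        rate = 180.0  # deg/s -> 90 deg in 0.5 s
        cfg = FusionConfig(gain=0.0)
        samp = ImuSample(0.0, np.array([0.0, 0.0, -1.0]),
                         axis * rate, np.array([1.0, 0.0, 0.0]))
        state = OrientationState(q=(1.0, 0.0, 0.0, 0.0))
        for _ in range(25):
            state = ahrs_step(state, samp, 0.02, cfg)
        w, x, y, z = state.q
        got = Rotation.from_quat([x, y, z, w])
        expected = Rotation.from_rotvec(np.radians(90.0) * axis)
        err = (got.inv() * expected).magnitude()
        assert math.degrees(err) < 0.2

    def test_unit_norm_preserved_every_step(self):
        rs = np.random.default_rng(9)
        cfg = FusionConfig()
        state = OrientationState(q=(1.0, 0.0, 0.0, 0.0))
        for _ in range(200):
            samp = ImuSample(
                0.0,
                rs.normal(0, 1, 3) + [1, 0, 0],
                rs.normal(0, 300, 3),
                rs.normal(0, 0.05, 3) + [0, 1, 0],
            )
            state = ahrs_step(state, samp, 0.02, cfg)
            assert abs(math.hypot(*state.q[:2], *state.q[2:]) - 1.0) < 1e-9
            dcm = quat_to_dcm(state.q)
            assert np.allclose(dcm.T @ dcm, np.eye(3), atol=1e-8)
            assert np.linalg.det(dcm) == pytest.approx(1.0, abs=1e-8)

    def test_nonfinite_sensor_values_rejected(self):
        samp = ImuSample(0.0, np.array([np.nan, 0.0, 0.0]),
                         np.zeros(3), np.array([0.0, 1.0, 0.0]))
        with pytest.raises(OrientationError):
            ahrs_step(OrientationState(q=(1.0, 0.0, 0.0, 0.0)), samp, 0.02)

    def test_nonpositive_dt_rejected(self):
        samp = ImuSample(0.0, np.array([1.0, 0.0, 0.0]),
                         np.zeros(3), np.array([0.0, 1.0, 0.0]))
        with pytest.raises(OrientationError):
            ahrs_step(OrientationState(q=(1.0, 0.0, 0.0, 0.0)), samp, 0.0)


class TestEstimateSeries:
    def test_static_recording_constant_theta(self):
        rec = make_recording(n=200)  # arm at nadir, 4 s
        series = estimate_series(rec)
        after = series.theta[50:]  # 1 s warm-up
        assert np.all(np.abs(after - after.mean()) < 0.5)
        # filtered and accel-only estimators agree on static data
        assert np.all(np.abs(series.theta[50:] - series.theta_accel[50:]) < 1.0)

    def test_rate_magnitude_is_euclidean_norm(self):
        gyro = np.tile([300.0, 400.0, 0.0], (10, 1))
        rec = make_recording(n=10, gyro=gyro)
        series = estimate_series(rec)
        np.testing.assert_allclose(series.rate_mag, 500.0)

    def test_tracks_simulator_ground_truth(self, quiet_throw_session):
        rec, truth = quiet_throw_session
        series = estimate_series(rec)
        rms = np.sqrt(np.mean((series.theta - truth.theta) ** 2))
        assert rms < 3.0

    def test_filter_rejects_throw_impulses_better_than_accel_only(self, quiet_throw_session):
        """High linear acceleration corrupts the accelerometer-only angle
        while the fused estimate stays near truth (shock tolerance)."""
        rec, truth = quiet_throw_session
        series = estimate_series(rec)
        win = np.zeros(len(rec), dtype=bool)
        for ev in truth.sport_events():
            lo = int((ev.onset - 0.5) * rec.fs)
            hi = int((ev.end + 0.5) * rec.fs)
            win[max(lo, 0):hi] = True
        filt = np.sqrt(np.mean((series.theta[win] - truth.theta[win]) ** 2))
        accel_only = np.sqrt(np.mean((series.theta_accel[win] - truth.theta[win]) ** 2))
        assert filt < 3.0 < accel_only
        # no post-impulse divergence: quiet tail re-converges
        assert abs(series.theta[-1] - truth.theta[-1]) < 2.0

    def test_theta_always_within_bounds(self, sports_series):
        assert np.all(sports_series.theta >= 0.0)
        assert np.all(sports_series.theta <= 180.0)

    def test_quaternions_unit_norm_along_series(self, sports_series):
        norms = np.linalg.norm(sports_series.quat, axis=1)
        assert np.max(np.abs(norms - 1.0)) < 1e-9

    def test_elevation_from_quats_matches_scalar(self, sports_series):
        idx = [0, 100, 500]
        batch = elevation_from_quats(sports_series.quat[idx])
        for j, i in enumerate(idx):
            scalar = elevation_from_state(
                OrientationState(q=tuple(sports_series.quat[i]))
            )
            assert batch[j] == pytest.approx(scalar, abs=1e-9)

    def test_heading_insensitive_elevation(self):
        """Magnetometer only steers heading: disabling it leaves theta alone."""
        script = syn.sports_script(2, 0, seed=21)
        rec, _ = syn.generate_session(script)
        with_mag = estimate_series(rec, FusionConfig(use_mag=True))
        without = estimate_series(rec, FusionConfig(use_mag=False))
        assert np.max(np.abs(with_mag.theta - without.theta)) < 1.0
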