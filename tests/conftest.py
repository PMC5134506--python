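import numpy as np
import pytest

from armtrack import synthetic as syn
from armtrack.orientation import estimate_series


@pytest.fixture(scope="session")
def sports_session():
    """8 throws + 8 serves, the detector demonstration pattern."""
    script = syn.sports_script(8, 8, seed=3)
    rec, truth = syn.generate_session(script)
    return rec, truth


@pytest.fixture(scope="session")
def sports_series(sports_session):
    rec, _ = sports_session
    return estimate_series(rec)


@pytest.fixture(scope="session")
def quiet_throw_session():
    """3 throws with all sensor noise switched off (ground-truth tracking)."""
    script = syn.sports_script(3, 0, seed=11)
    rec, truth = syn.generate_session(script, syn.NoiseConfig.zero())
    return rec, truth


@pytest.fixture(scope="session")
def recovery():
    """Trained model + 20-session randomized-protocol evaluation."""
    from armtrack.benchmark import recovery_benchmark

    return recovery_benchmark(seed=1, n_sessions=20)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def make_recording(n=100, fs=50.0, seed=0, accel=None, gyro=None):
    """Small hand-rolled recording: static gravity unless overridden."""
    from armtrack.imu import ImuRecording

    rs = np.random.default_rng(seed)
    t = np.arange(n) / fs
    if accel is None:
        accel = np.tile([1.0, 0.0, 0.0], (n, 1))  # arm hanging at nadir
    if gyro is None:
        gyro = np.zeros((n, 3))
    mag = np.tile([0.0, 1.0, 0.0], (n, 1))
    return ImuRecording(fs=fs, t=t, accel=np.asarray(accel, float),
                        gyro=np.asarray(gyro, float), mag=mag,
                        meta={"seed": seed, "rng": rs})
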