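"""Ground-truthed simulator of arm-worn IMU recordings.

Emulates 50 Hz upper-arm recordings of overhead sport motions (baseball
throws, volleyball serves), seven resisted shoulder exercises and rest.
The arm's orientation is a smooth time-parameterised rotation built from
minimum-jerk interpolation between key poses expressed in three angles:

* ``theta`` -- arm elevation, the angle between the along-arm device
  x-axis and nadir (0 = hanging, 180 = overhead);
* ``psi``   -- azimuth (compass heading) of the arm;
* ``roll``  -- rotation about the arm's own axis (internal/external
  shoulder rotation).

The device->world rotation is ``R = Rz(psi) @ Ry(90deg - theta) @
Rx(roll)``. The emitted gyroscope signal is the analytic angular velocity
of this rotation expressed in the device frame; the accelerometer senses
the device-frame gravity direction (a hanging arm reads a_x = +1 g) plus
the linear acceleration of a sensor located a fixed lever arm along the
arm; the magnetometer senses the device-frame North direction. White
noise and a constant per-session gyro bias are added on top.

Throws are internal-rotation-dominant (fast roll sweep about the arm
axis, peak rates up to roughly 2400 deg/s), serves are elevation-plane
swings (fast theta sweep, several hundred deg/s), and every resistance
exercise stays well below the 400 deg/s stage-1 rate threshold while
elevated -- a Flexion rep exceeds 45 deg slowly, an External Rotation at
the Side stays at low elevation. Every event is logged with its onset and
peak-rate time, so detector and classifier output can be scored against
ground truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from .imu import DEFAULT_FS, ImuRecording

GRAVITY = 9.81          # m/s^2
LEVER_ARM_M = 0.13      # sensor distance from the shoulder pivot, m
REST_THETA = 8.0        # hanging-arm elevation, deg

# Table of simulated activities
BASEBALL_THROW = "baseball_throw"
VOLLEYBALL_SERVE = "volleyball_serve"
EXT_ROT_90 = "external_rotation_90"
THROW_DECELERATION = "throw_deceleration"
THROW_ACCELERATION = "throw_acceleration"
FLEXION = "flexion"
EXTENSION = "extension"
EXT_ROT_SIDE = "external_rotation_side"
SCAPULAR_PUNCH = "scapular_punch"
REST = "rest"

SPORTS = {BASEBALL_THROW: "Throw", VOLLEYBALL_SERVE: "Serve"}
EXERCISES = (
    EXT_ROT_90,
    THROW_DECELERATION,
    THROW_ACCELERATION,
    FLEXION,
    EXTENSION,
    EXT_ROT_SIDE,
    SCAPULAR_PUNCH,
)
ACTIVITIES = tuple(SPORTS) + EXERCISES + (REST,)


class SyntheticError(Exception):
    pass


@dataclass
class NoiseConfig:
    """Sensor imperfection model (plausible for consumer MEMS parts)."""

    gyro_noise_dps: float = 1.0     # white noise, rms
    gyro_bias_dps: float = 0.5      # per-axis constant bias, sd across sessions
    accel_noise_g: float = 0.02
    mag_noise: float = 0.01
    gyro_clip_dps: float | None = None  # per-axis full-scale clipping, off by default

    @classmethod
    def zero(cls) -> "NoiseConfig":
        return cls(0.0, 0.0, 0.0, 0.0, None)


@dataclass(frozen=True)
class SessionScript:
    """Ordered (activity, repetitions) blocks plus the session seed."""

    blocks: tuple
    seed: int = 0
    subject_scale: float = 1.0       # per-subject speed scaling (+-15%)
    gap_range: tuple = (1.5, 3.5)    # rest gaps between sport reps, s

    def __post_init__(self) -> None:
        for name, reps in self.blocks:
            if name not in ACTIVITIES:
                raise SyntheticError(f"unknown activity template {name!r}")
            if reps < 1:
                raise SyntheticError("repetitions must be >= 1")
        if self.gap_range[0] < 1.0:
            raise SyntheticError("rest gaps must be >= 1 s to keep events separable")


@dataclass(frozen=True)
class GtEvent:
    activity: str
    onset: float           # s
    end: float             # s
    peak_rate_time: float  # s, from the noiseless gyro
    peak_rate_dps: float


@dataclass
class GroundTruth:
    """Per-event truth plus the noiseless kinematics of the session."""

    events: list
    counts: dict
    t: np.ndarray
    theta: np.ndarray          # true elevation series, deg
    quat: np.ndarray           # true attitude, (n, 4) w,x,y,z
    omega_dev: np.ndarray      # noiseless device-frame rates, deg/s

    @property
    def sport_counts(self) -> dict:
        return {
            cls: self.counts.get(act, 0) for act, cls in SPORTS.items()
        }

    def sport_events(self) -> list:
        return [e for e in self.events if e.activity in SPORTS]


# ---------------------------------------------------------------------------
# activity templates: lists of (dt_from_previous_key, theta, psi, roll)
# ---------------------------------------------------------------------------

def _speed(rng, k: float, jitter: float = 0.08, lo: float = 0.7, hi: float = 1.25) -> float:
    return float(np.clip(k * (1.0 + jitter * rng.standard_normal()), lo, hi))


def _throw(rng, k):
    kk = _speed(rng, k)
    s = 1.0 / kk
    sweep = 150.0 * rng.uniform(0.9, 1.1)
    cock = -65.0 + 5.0 * rng.standard_normal()
    return [
        (0.0, 14.0, -5.0, 0.0),
        (0.50 * s, 96.0 + 3.0 * rng.standard_normal(), -30.0, cock),
        (0.16 * s, 101.0, 25.0, cock + sweep),
        (0.75 * s, 40.0, 30.0, 0.0),
    ]


def _serve(rng, k):
    kk = _speed(rng, k)
    s = 1.0 / kk
    top = 150.0 + 4.0 * rng.standard_normal()
    return [
        (0.0, 20.0, 0.0, 5.0),
        (0.65 * s, top, -10.0, 25.0),
        (0.22 * s, 55.0, 0.0, 0.0),
        (0.50 * s, 28.0, 0.0, 0.0),
    ]


def _ext_rot_90(rng, k):
    kk = _speed(rng, k, jitter=0.05)
    s = 1.0 / kk
    return [
        (0.0, 88.0, 0.0, 10.0),
        (1.2 * s, 90.0, 0.0, -55.0 - 5.0 * rng.standard_normal()),
        (1.2 * s, 88.0, 0.0, 10.0),
    ]


def _throw_decel(rng, k):
    kk = _speed(rng, k, jitter=0.05)
    s = 1.0 / kk
    return [
        (0.0, 20.0, -10.0, 0.0),
        (1.4 * s, 95.0, -15.0, -60.0),
        (1.5 * s, 20.0, -10.0, 0.0),
    ]


def _throw_accel(rng, k):
    kk = _speed(rng, k, jitter=0.05)
    s = 1.0 / kk
    return [
        (0.0, 90.0, -20.0, -55.0),
        (1.3 * s, 45.0, 10.0, 20.0),
        (1.5 * s, 90.0, -20.0, -55.0),
    ]


def _flexion(rng, k):
    kk = _speed(rng, k, jitter=0.05)
    s = 1.0 / kk
    return [
        (0.0, 12.0, 0.0, 0.0),
        (2.0 * s, 165.0 + 2.0 * rng.standard_normal(), 0.0, 0.0),
        (2.0 * s, 12.0, 0.0, 0.0),
    ]


def _extension(rng, k):
    kk = _speed(rng, k, jitter=0.05)
    s = 1.0 / kk
    return [
        (0.0, 65.0, 0.0, 0.0),
        (1.3 * s, 8.0, 0.0, 0.0),
        (1.5 * s, 65.0, 0.0, 0.0),
    ]


def _ext_rot_side(rng, k):
    kk = _speed(rng, k, jitter=0.05)
    s = 1.0 / kk
    return [
        (0.0, 14.0, 0.0, 0.0),
        (1.1 * s, 16.0, 35.0, 60.0 + 5.0 * rng.standard_normal()),
        (1.1 * s, 14.0, 0.0, 0.0),
    ]


def _scap_punch(rng, k):
    kk = _speed(rng, k, jitter=0.05)
    s = 1.0 / kk
    return [
        (0.0, 82.0, 0.0, 0.0),
        (0.8 * s, 86.0, 22.0, 0.0),
        (0.8 * s, 82.0, 0.0, 0.0),
    ]


def _rest(rng, k):
    return [(0.0, REST_THETA, 0.0, 0.0), (2.0, REST_THETA, 0.0, 0.0)]


TEMPLATES = {
    BASEBALL_THROW: _throw,
    VOLLEYBALL_SERVE: _serve,
    EXT_ROT_90: _ext_rot_90,
    THROW_DECELERATION: _throw_decel,
    THROW_ACCELERATION: _throw_accel,
    FLEXION: _flexion,
    EXTENSION: _extension,
    EXT_ROT_SIDE: _ext_rot_side,
    SCAPULAR_PUNCH: _scap_punch,
    REST: _rest,
}


# ---------------------------------------------------------------------------
# trajectory synthesis
# ---------------------------------------------------------------------------

def _minjerk_eval(tk: np.ndarray, vk: np.ndarray, t: np.ndarray):
    """Piecewise minimum-jerk interpolation of keyed channels.

    ``tk`` (K,) strictly increasing key times, ``vk`` (K, c) channel
    values. Returns values (n, c) and analytic rates (n, c). Velocity and
    acceleration vanish at every key, so the composite trajectory is
    twice continuously differentiable.
    """
    j = np.clip(np.searchsorted(tk, t, side="right") - 1, 0, len(tk) - 2)
    dt = tk[j + 1] - tk[j]
    u = np.clip((t - tk[j]) / dt, 0.0, 1.0)
    s = u ** 3 * (10.0 - 15.0 * u + 6.0 * u ** 2)
    sdot = 30.0 * u ** 2 * (1.0 - u) ** 2
    dv = vk[j + 1] - vk[j]
    val = vk[j] + dv * s[:, None]
    rate = dv * (sdot / dt)[:, None]
    return val, rate


def _kinematics(tk: np.ndarray, vk: np.ndarray, t: np.ndarray):
    """True attitude, device rates, and sensor-truth channels on a grid."""
    ang, angdot = _minjerk_eval(tk, vk, t)
    theta, psi, roll = ang[:, 0], ang[:, 1], ang[:, 2]
    thetad, psid, rolld = angdot[:, 0], angdot[:, 1], angdot[:, 2]
    alpha = 90.0 - theta
    alphad = -thetad

    rot = Rotation.from_euler("ZYX", np.column_stack([psi, alpha, roll]), degrees=True)
    dcm = rot.as_matrix()                        # (n, 3, 3) device -> world
    q_xyzw = rot.as_quat()
    quat = np.column_stack([q_xyzw[:, 3], q_xyzw[:, 0], q_xyzw[:, 1], q_xyzw[:, 2]])
    # keep a continuous quaternion track (q and -q are the same rotation)
    flips = np.cumsum(np.sum(quat[1:] * quat[:-1], axis=1) < 0) % 2
    quat[1:][flips == 1] *= -1.0

    sps, cps = np.sin(np.radians(psi)), np.cos(np.radians(psi))
    sal, cal = np.sin(np.radians(alpha)), np.cos(np.radians(alpha))
    y_psi = np.column_stack([-sps, cps, np.zeros_like(sps)])
    x_arm = np.column_stack([cal * cps, cal * sps, -sal])
    omega_world = (
        psid[:, None] * np.array([0.0, 0.0, 1.0])
        + alphad[:, None] * y_psi
        + rolld[:, None] * x_arm
    )
    omega_dev = np.einsum("nji,nj->ni", dcm, omega_world)  # R^T w, deg/s

    # sensor lever arm: linear acceleration of a point L along the arm
    p = LEVER_ARM_M * x_arm
    fs = 1.0 / (t[1] - t[0]) if len(t) > 1 else DEFAULT_FS
    v = np.gradient(p, axis=0) * fs
    a_lin = np.gradient(v, axis=0) * fs
    grav_minus_acc = np.array([0.0, 0.0, -1.0]) - a_lin / GRAVITY
    accel_dev = np.einsum("nji,nj->ni", dcm, grav_minus_acc)
    mag_dev = np.einsum("nji,nj->ni", dcm, np.broadcast_to([1.0, 0.0, 0.0], (len(t), 3)))
    return quat, theta, omega_dev, accel_dev, mag_dev


def generate_session(script: SessionScript, noise: NoiseConfig | None = None,
                     fs: float = DEFAULT_FS):
    """Synthesise one session: ``(ImuRecording, GroundTruth)``.

    Blocks are rendered in order. Sport repetitions are separated by
    randomised rest gaps and each logged as one event; exercise
    repetitions run as contiguous cycles within their block, one event
    per cycle. Identical scripts (same seed) produce byte-identical
    output.
    """
    noise = NoiseConfig() if noise is None else noise
    rng = np.random.default_rng(script.seed)

    keys = [(0.0, REST_THETA, 0.0, 0.0)]
    cur_t = 1.0
    keys.append((cur_t, REST_THETA, 0.0, 0.0))
    heading = 0.0
    raw_events = []   # (activity, onset, end)
    counts: dict = {}

    def _append(rel_keys, t_arrival):
        """Append a transition to the first key pose, then the rest."""
        nonlocal cur_t
        first = rel_keys[0]
        keys.append((t_arrival, first[1], first[2] + heading, first[3]))
        cur_t = t_arrival
        for dt, th, ps, rl in rel_keys[1:]:
            cur_t += dt
            keys.append((cur_t, th, ps + heading, rl))

    for name, reps in script.blocks:
        if name != REST:
            heading += rng.uniform(-60.0, 60.0)  # compass-heading variation
        counts[name] = counts.get(name, 0) + (reps if name != REST else 0)
        builder = TEMPLATES[name]
        if name in SPORTS:
            for _ in range(reps):
                gap = rng.uniform(*script.gap_range)
                rel = builder(rng, script.subject_scale)
                onset = cur_t + gap
                _append(rel, onset)
                raw_events.append((name, onset, cur_t))
        elif name == REST:
            rel = builder(rng, script.subject_scale)
            _append(rel, cur_t + 1.0)
            hold = max(0.0, reps - 1) * 2.0
            if hold:
                cur_t += hold
                last = keys[-1]
                keys.append((cur_t, last[1], last[2], last[3]))
        else:
            gap = rng.uniform(*script.gap_range)
            rel = builder(rng, script.subject_scale)
            _append([rel[0]], cur_t + gap)
            for _ in range(reps):
                cyc = builder(rng, script.subject_scale)
                onset = cur_t
                for dt, th, ps, rl in cyc[1:]:
                    cur_t += dt
                    keys.append((cur_t, th, ps + heading, rl))
                raw_events.append((name, onset, cur_t))
    # wind down to rest
    keys.append((cur_t + 2.0, REST_THETA, heading, 0.0))
    keys.append((cur_t + 4.0, REST_THETA, heading, 0.0))
    cur_t += 4.0

    tk = np.array([k[0] for k in keys])
    vk = np.array([[k[1], k[2], k[3]] for k in keys])
    n = int(math.floor(cur_t * fs)) + 1
    t = np.arange(n) / fs
    quat, theta, omega_dev, accel_dev, mag_dev = _kinematics(tk, vk, t)

    rate_true = np.linalg.norm(omega_dev, axis=1)
    events = []
    for name, onset, end in raw_events:
        lo = int(round(onset * fs))
        hi = min(int(round(end * fs)) + 1, n)
        i = lo + int(np.argmax(rate_true[lo:hi]))
        events.append(
            GtEvent(
                activity=name,
                onset=onset,
                end=end,
                peak_rate_time=float(t[i]),
                peak_rate_dps=float(rate_true[i]),
            )
        )

    gyro = omega_dev + noise.gyro_bias_dps * rng.standard_normal(3)
    gyro = gyro + noise.gyro_noise_dps * rng.standard_normal(gyro.shape)
    if noise.gyro_clip_dps is not None:
        gyro = np.clip(gyro, -noise.gyro_clip_dps, noise.gyro_clip_dps)
    accel = accel_dev + noise.accel_noise_g * rng.standard_normal(accel_dev.shape)
    mag = mag_dev + noise.mag_noise * rng.standard_normal(mag_dev.shape)

    rec = ImuRecording(
        fs=fs, t=t, accel=accel, gyro=gyro, mag=mag,
        meta={"seed": script.seed, "subject_scale": script.subject_scale,
              "blocks": list(script.blocks)},
    )
    truth = GroundTruth(
        events=events, counts=counts, t=t, theta=theta, quat=quat,
        omega_dev=omega_dev,
    )
    return rec, truth


# ---------------------------------------------------------------------------
# benchmark protocol
# ---------------------------------------------------------------------------

N_SUBJECTS = 11


@dataclass
class BenchmarkSuite:
    """Per-subject control and randomised session scripts."""

    control: list = field(default_factory=list)
    randomized: list = field(default_factory=list)


def default_benchmark_suite(seed: int = 0, n_subjects: int = N_SUBJECTS) -> BenchmarkSuite:
    """Scripts mimicking the two acquisition protocols.

    Every simulated subject gets a control session -- the seven resisted
    exercises then the two sport activities, fixed order, eight
    repetitions each -- and a randomised session with shuffled activity
    order, 2-6 repetitions per exercise and 4-12 per sport activity.
    Subjects carry a persistent +-15% kinematic speed scale emulating
    varying levels of overhead throwing experience.
    """
    rng = np.random.default_rng(seed)
    suite = BenchmarkSuite()
    control_blocks = tuple((name, 8) for name in EXERCISES) + (
        (BASEBALL_THROW, 8),
        (VOLLEYBALL_SERVE, 8),
    )
    for _ in range(n_subjects):
        scale = float(rng.uniform(0.85, 1.15))
        suite.control.append(
            SessionScript(
                blocks=control_blocks,
                seed=int(rng.integers(2 ** 31)),
                subject_scale=scale,
            )
        )
        names = list(EXERCISES) + [BASEBALL_THROW, VOLLEYBALL_SERVE]
        rng.shuffle(names)
        blocks = tuple(
            (name, int(rng.integers(4, 13)) if name in SPORTS else int(rng.integers(2, 7)))
            for name in names
        )
        suite.randomized.append(
            SessionScript(
                blocks=blocks,
                seed=int(rng.integers(2 ** 31)),
                subject_scale=scale,
            )
        )
    return suite


def exercises_only_script(seed: int = 0, reps: int = 4,
                          subject_scale: float = 1.0) -> SessionScript:
    """Negative-control session containing only the null-class exercises."""
    return SessionScript(
        blocks=tuple((name, reps) for name in EXERCISES),
        seed=seed,
        subject_scale=subject_scale,
    )


def sports_script(n_throws: int = 8, n_serves: int = 8, seed: int = 0,
                  subject_scale: float = 1.0) -> SessionScript:
    """Throws-then-serves session (the detector demonstration pattern).

    Either count may be zero; empty blocks are simply dropped.
    """
    blocks = tuple(
        (name, reps)
        for name, reps in ((BASEBALL_THROW, n_throws), (VOLLEYBALL_SERVE, n_serves))
        if reps > 0
    )
    return SessionScript(blocks=blocks, seed=seed, subject_scale=subject_scale)
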