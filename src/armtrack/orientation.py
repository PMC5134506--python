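"""AHRS sensor fusion and arm-elevation estimation.

Two estimators of the arm elevation angle theta -- the angle between the
device's along-arm x-axis and nadir -- are provided:

* ``elevation_from_accel``: the accelerometer-only estimate
  ``theta = arccos(a_x / ||a||)``. Valid when the sensed acceleration is
  dominated by gravity; corrupted whenever the arm itself accelerates,
  which is exactly the case during a throw.
* ``elevation_from_state``: the filtered estimate derived from the fused
  attitude, ``theta = arccos((DCM @ [1,0,0]) . [0,0,-1])``, where the DCM
  rotates device-frame vectors into the world frame.

The fusion filter is a quaternion complementary filter of the classic
propagate-then-correct form: the gyroscope rates propagate the attitude
each step, and a small fraction (``gain``) of the observed gravity/North
direction error is fed back as a body-frame correction. The accelerometer
correction is gated down during high-rate or high-|a| transients so that
shock and vibration (ball release, impact) cannot drag the estimate; drift
is re-absorbed once the signal is quiet again. The magnetometer only
corrects heading -- the horizontal reference is built from the measured
field -- so magnetic distortion cannot corrupt elevation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .imu import ImuRecording, ImuSample

_DEG = math.pi / 180.0


class OrientationError(Exception):
    pass


class UndefinedAngleError(OrientationError):
    """Raised when an angle is requested for a (near-)zero vector."""


# ---------------------------------------------------------------------------
# quaternion helpers (w, x, y, z convention; device -> world rotation)
# ---------------------------------------------------------------------------

def quat_multiply(p, q):
    pw, px, py, pz = p
    qw, qx, qy, qz = q
    return (
        pw * qw - px * qx - py * qy - pz * qz,
        pw * qx + px * qw + py * qz - pz * qy,
        pw * qy - px * qz + py * qw + pz * qx,
        pw * qz + px * qy - py * qx + pz * qw,
    )


def quat_from_rotvec(v) -> tuple:
    """Unit quaternion for a rotation vector (axis * angle, radians)."""
    x, y, z = v
    angle = math.sqrt(x * x + y * y + z * z)
    if angle < 1e-12:
        return (1.0, 0.5 * x, 0.5 * y, 0.5 * z)
    half = 0.5 * angle
    s = math.sin(half) / angle
    return (math.cos(half), x * s, y * s, z * s)


def quat_normalize(q) -> tuple:
    w, x, y, z = q
    n = math.sqrt(w * w + x * x + y * y + z * z)
    return (w / n, x / n, y / n, z / n)


def quat_to_dcm(q) -> np.ndarray:
    """3x3 rotation matrix mapping device-frame vectors to the world frame."""
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )


def quats_to_dcm(quats: np.ndarray) -> np.ndarray:
    """Vectorised ``(n, 4) -> (n, 3, 3)`` version of :func:`quat_to_dcm`."""
    w, x, y, z = quats[:, 0], quats[:, 1], quats[:, 2], quats[:, 3]
    out = np.empty((quats.shape[0], 3, 3))
    out[:, 0, 0] = 1 - 2 * (y * y + z * z)
    out[:, 0, 1] = 2 * (x * y - w * z)
    out[:, 0, 2] = 2 * (x * z + w * y)
    out[:, 1, 0] = 2 * (x * y + w * z)
    out[:, 1, 1] = 1 - 2 * (x * x + z * z)
    out[:, 1, 2] = 2 * (y * z - w * x)
    out[:, 2, 0] = 2 * (x * z - w * y)
    out[:, 2, 1] = 2 * (y * z + w * x)
    out[:, 2, 2] = 1 - 2 * (x * x + y * y)
    return out


# ---------------------------------------------------------------------------
# state / config
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OrientationState:
    """Unit-quaternion attitude estimate at time ``t`` (device -> world)."""

    q: tuple
    t: float = 0.0

    @property
    def dcm(self) -> np.ndarray:
        return quat_to_dcm(self.q)


@dataclass
class FusionConfig:
    """Tunables of the complementary filter.

    gain
        Dimensionless per-sample correction fraction applied to the
        measured orientation error (0 disables correction entirely; at
        50 Hz the default 0.1 gives a ~0.2 s correction time constant).
    mag_weight
        Relative weight of the magnetometer (heading) error term.
    use_mag
        Disable to run tilt-only fusion (heading then drifts freely).
    accel_gate
        ``(lo, hi)`` in g: the gravity correction has full weight while
        ``| ||a|| - 1 | < lo`` and is faded linearly to zero at ``hi``.
        Rejects linear-acceleration transients.
    rate_gate_dps
        Gravity correction is disabled above this rotation rate.
    init
        ``"triad"`` initialises from the first accel+mag sample,
        ``"identity"`` from the identity quaternion.
    """

    gain: float = 0.1
    mag_weight: float = 0.5
    use_mag: bool = True
    accel_gate: tuple = (0.05, 0.2)
    rate_gate_dps: float = 250.0
    init: str = "triad"


@dataclass
class OrientationSeries:
    """Per-sample fusion output aligned with the parent recording."""

    t: np.ndarray
    fs: float
    quat: np.ndarray       # (n, 4) w,x,y,z
    theta: np.ndarray      # filtered elevation, deg, in [0, 180]
    theta_accel: np.ndarray  # accelerometer-only elevation, deg
    rate_mag: np.ndarray   # gyro magnitude, deg/s

    def __len__(self) -> int:
        return int(self.t.shape[0])


# ---------------------------------------------------------------------------
# elevation estimators
# ---------------------------------------------------------------------------

def elevation_from_accel(accel) -> float | np.ndarray:
    """Accelerometer-only arm elevation, degrees in [0, 180].

    ``theta = arccos(a_x / ||a||)`` where x points along the arm. Accepts a
    single 3-vector or an ``(n, 3)`` array.
    """
    a = np.asarray(accel, dtype=float)
    norm = np.linalg.norm(a, axis=-1)
    if np.any(norm <= 1e-6):
        raise UndefinedAngleError("acceleration magnitude too small for an elevation angle")
    c = np.clip(a[..., 0] / norm, -1.0, 1.0)
    theta = np.degrees(np.arccos(c))
    return float(theta) if theta.ndim == 0 else theta


def elevation_from_state(state: OrientationState) -> float:
    """Filtered arm elevation from a fused attitude, degrees in [0, 180].

    Angle between the world-frame image of the device x-axis and nadir:
    ``arccos((DCM @ [1,0,0]) . [0,0,-1])``.
    """
    return _elevation_from_quat(state.q)


def _elevation_from_quat(q) -> float:
    # (DCM @ e_x) . (0,0,-1) = -DCM[2,0]
    w, x, y, z = q
    c = -(2 * (x * z - w * y))
    return math.degrees(math.acos(max(-1.0, min(1.0, c))))


def elevation_from_quats(quats: np.ndarray) -> np.ndarray:
    """Vectorised filtered elevation for an ``(n, 4)`` quaternion array."""
    w, x, y, z = quats[:, 0], quats[:, 1], quats[:, 2], quats[:, 3]
    c = np.clip(-(2 * (x * z - w * y)), -1.0, 1.0)
    return np.degrees(np.arccos(c))


def axis_elevations(quats: np.ndarray) -> np.ndarray:
    """Per-axis elevation relative to gravity, degrees, shape ``(n, 3)``.

    Column i is the angle between device axis e_i (rotated to the world
    frame) and nadir; column 0 is the arm elevation theta.
    """
    dcm = quats_to_dcm(quats)
    cosang = np.clip(-dcm[:, 2, :], -1.0, 1.0)  # (R e_i).(0,0,-1) = -R[2,i]
    return np.degrees(np.arccos(cosang))


def triad_init(accel, mag) -> tuple:
    """Initial attitude from one accelerometer + magnetometer sample.

    Builds matched orthonormal triads in the device frame (measured nadir
    and North) and the world frame and solves for the rotation directly.
    """
    a = np.asarray(accel, dtype=float)
    m = np.asarray(mag, dtype=float)
    if np.linalg.norm(a) < 1e-6 or np.linalg.norm(m) < 1e-6:
        raise UndefinedAngleError("cannot initialise attitude from near-zero accel/mag")
    d = a / np.linalg.norm(a)            # device-frame nadir (gravity convention)
    e = np.cross(d, m)
    if np.linalg.norm(e) < 1e-6:         # field parallel to gravity: heading undefined
        e = np.cross(d, np.array([0.0, 1.0, 0.0]))
        if np.linalg.norm(e) < 1e-6:
            e = np.cross(d, np.array([0.0, 0.0, 1.0]))
    e = e / np.linalg.norm(e)
    f = np.cross(d, e)
    wd = np.array([0.0, 0.0, -1.0])
    we = np.array([0.0, -1.0, 0.0])      # cross(nadir, North)
    wf = np.cross(wd, we)
    T = np.column_stack([d, e, f])
    W = np.column_stack([wd, we, wf])
    R = W @ T.T
    # rotation matrix -> quaternion (scipy convention shuffle kept local)
    from scipy.spatial.transform import Rotation

    x, y, z, w = Rotation.from_matrix(R).as_quat()
    return quat_normalize((w, x, y, z))


# ---------------------------------------------------------------------------
# the filter
# ---------------------------------------------------------------------------

def _step(q, ax, ay, az, gx, gy, gz, mx, my, mz, dt, cfg: FusionConfig,
          prev_g=None) -> tuple:
    """One propagate-then-correct step on plain floats (hot loop)."""
    # propagate by the gyro rate (trapezoidal average when available)
    if prev_g is not None:
        wx = 0.5 * (gx + prev_g[0]) * _DEG
        wy = 0.5 * (gy + prev_g[1]) * _DEG
        wz = 0.5 * (gz + prev_g[2]) * _DEG
    else:
        wx, wy, wz = gx * _DEG, gy * _DEG, gz * _DEG
    q = quat_multiply(q, quat_from_rotvec((wx * dt, wy * dt, wz * dt)))

    if cfg.gain > 0.0:
        ex = ey = ez = 0.0
        w, x, y, z = q
        # gravity correction, gated on accel-norm and rate
        anorm = math.sqrt(ax * ax + ay * ay + az * az)
        rate = math.sqrt(gx * gx + gy * gy + gz * gz)
        lo, hi = cfg.accel_gate
        wa = 1.0 - (abs(anorm - 1.0) - lo) / (hi - lo)
        wa = max(0.0, min(1.0, wa))
        if rate > cfg.rate_gate_dps:
            wa = 0.0
        if wa > 0.0 and anorm > 1e-6:
            # predicted device-frame nadir = R^T (0,0,-1) = -third row of R
            px = -(2 * (x * z - w * y))
            py = -(2 * (y * z + w * x))
            pz = -(1 - 2 * (x * x + y * y))
            dx, dy, dz = ax / anorm, ay / anorm, az / anorm
            ex += wa * (dy * pz - dz * py)
            ey += wa * (dz * px - dx * pz)
            ez += wa * (dx * py - dy * px)
        if cfg.use_mag:
            mnorm = math.sqrt(mx * mx + my * my + mz * mz)
            if mnorm > 1e-6:
                hx_, hy_, hz_ = mx / mnorm, my / mnorm, mz / mnorm
                # world-frame field, then a dip-free reference in the x-z plane
                R = quat_to_dcm(q)
                hw = R @ (hx_, hy_, hz_)
                bx = math.hypot(hw[0], hw[1])
                bz = hw[2]
                bn = math.hypot(bx, bz)
                if bn > 1e-6:
                    ref = (bx / bn, 0.0, bz / bn)
                    pm = R.T @ ref
                    ex += cfg.mag_weight * (hy_ * pm[2] - hz_ * pm[1])
                    ey += cfg.mag_weight * (hz_ * pm[0] - hx_ * pm[2])
                    ez += cfg.mag_weight * (hx_ * pm[1] - hy_ * pm[0])
        g = cfg.gain
        q = quat_multiply(q, quat_from_rotvec((g * ex, g * ey, g * ez)))
    return quat_normalize(q)


def ahrs_step(state: OrientationState, sample: ImuSample, dt: float,
              cfg: FusionConfig | None = None) -> OrientationState:
    """Advance the attitude estimate by one sample.

    Propagates the quaternion by the gyro rate over ``dt``, applies the
    gated gravity/North correction scaled by ``cfg.gain``, and
    renormalises.
    """
    if dt <= 0:
        raise OrientationError(f"dt must be positive, got {dt}")
    cfg = cfg or FusionConfig()
    vals = np.concatenate([sample.accel, sample.gyro, sample.mag])
    if not np.all(np.isfinite(vals)):
        raise OrientationError("non-finite sensor values in ahrs_step")
    q = _step(state.q, *vals.tolist(), dt, cfg)
    return OrientationState(q=q, t=state.t + dt)


def estimate_series(rec: ImuRecording, cfg: FusionConfig | None = None) -> OrientationSeries:
    """Run the filter over a whole recording (one state per sample).

    Returns the filtered elevation series, the accelerometer-only
    elevation, the per-sample angular-rate magnitude and the full
    quaternion track for downstream feature extraction. Processing is
    strictly causal.
    """
    cfg = cfg or FusionConfig()
    n = len(rec)
    if cfg.init == "triad":
        q = triad_init(rec.accel[0], rec.mag[0])
    else:
        q = (1.0, 0.0, 0.0, 0.0)
    quats = np.empty((n, 4))
    quats[0] = q
    acc = rec.accel
    gyr = rec.gyro
    mag = rec.mag
    t = rec.t
    prev = (gyr[0, 0], gyr[0, 1], gyr[0, 2])
    for i in range(1, n):
        dt = float(t[i] - t[i - 1])
        q = _step(
            q,
            acc[i, 0], acc[i, 1], acc[i, 2],
            gyr[i, 0], gyr[i, 1], gyr[i, 2],
            mag[i, 0], mag[i, 1], mag[i, 2],
            dt, cfg,
            prev_g=prev,
        )
        prev = (gyr[i, 0], gyr[i, 1], gyr[i, 2])
        quats[i] = q
    return OrientationSeries(
        t=t.copy(),
        fs=rec.fs,
        quat=quats,
        theta=elevation_from_quats(quats),
        theta_accel=elevation_from_accel(acc),
        rate_mag=rec.rate_magnitude,
    )
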