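"""Stage-1 gesture spotting: rule-based detection and segment extraction.

Locating a candidate gesture inside a continuous stream (the windowing
problem) is handled by a causal threshold rule on quantities that are
available in real time: the filtered arm elevation and the angular-rate
magnitude. A sport overhead motion is flagged whenever

    (elevation > 45 deg) AND (angular rate > 400 deg/s)

both hold strictly. Slow elevated motions (e.g. a resisted flexion
exercise) fail the rate condition; fast motion with the arm down fails the
elevation condition. Raw triggers closer together than a refractory period
are merged into one detection anchored at the sample of maximum rate, and
a fixed window around the anchor is cut out for the stage-2 classifier.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .imu import ImuRecording
from .orientation import OrientationSeries


class SpottingError(Exception):
    pass


@dataclass(frozen=True)
class DetectionRule:
    """Conjunction thresholds of the stage-1 detector."""

    elevation_deg: float = 45.0
    rate_dps: float = 400.0
    refractory_s: float = 1.0

    def __post_init__(self) -> None:
        if self.elevation_deg <= 0 or self.rate_dps <= 0 or self.refractory_s <= 0:
            raise SpottingError("detection thresholds must be positive")


@dataclass(frozen=True)
class DetectionEvent:
    """One merged stage-1 detection, anchored at the peak-rate sample."""

    index: int          # trigger (anchor) sample index
    time: float         # trigger time, s
    first_index: int    # first raw trigger of the merged run
    last_index: int     # last raw trigger of the merged run


@dataclass
class Segment:
    """Fixed-width 9-channel window around a stage-1 detection."""

    t0: float                 # time of the first (possibly padded) sample
    fs: float
    accel: np.ndarray         # (m, 3) g
    gyro: np.ndarray          # (m, 3) deg/s
    mag: np.ndarray           # (m, 3)
    quat: np.ndarray          # (m, 4) fused attitude
    theta: np.ndarray         # (m,) filtered elevation, deg
    trigger_offset: int       # anchor position within the window
    padded: bool = False
    meta: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return int(self.gyro.shape[0])


def spot(theta, rate_mag, fs: float, rule: DetectionRule | None = None) -> list[DetectionEvent]:
    """Apply the stage-1 conjunction rule and merge refractory runs.

    ``theta`` and ``rate_mag`` must be aligned, equal-length series
    sampled at ``fs``. A raw trigger fires at every sample where both
    thresholds are strictly exceeded. A raw trigger starts a new event
    only when the previous counted trigger lies more than the refractory
    period in the past (the same debounce rule used by the event
    counter); every raw trigger inside the refractory window is absorbed
    into the event, which is anchored at the sample of maximum rate
    magnitude among them. The computation is causal: an event is final
    one refractory period after its counted trigger.
    """
    rule = rule or DetectionRule()
    theta = np.asarray(theta, dtype=float)
    rate = np.asarray(rate_mag, dtype=float)
    if theta.shape != rate.shape:
        raise SpottingError("elevation and rate series must be aligned and equal length")
    raw = np.flatnonzero((theta > rule.elevation_deg) & (rate > rule.rate_dps))
    if raw.size == 0:
        return []
    gap = int(round(rule.refractory_s * fs))
    # debounce against the last *counted* trigger (greedy packing, so the
    # event count can only shrink when either threshold is raised)
    events = []
    last = None
    for idx in raw:
        if last is not None and idx - last <= gap:
            continue
        absorbed = raw[(raw >= idx) & (raw <= idx + gap)]
        anchor = int(absorbed[np.argmax(rate[absorbed])])
        events.append(
            DetectionEvent(
                index=anchor,
                time=anchor / fs,
                first_index=int(idx),
                last_index=int(absorbed[-1]),
            )
        )
        last = idx
    return events


def extract(rec: ImuRecording, orient: OrientationSeries, event: DetectionEvent,
            window_s: float = 2.0, pre_share: float = 0.4) -> Segment:
    """Cut a fixed-size window around a detection.

    The window spans ``[trigger - pre_share*window, trigger +
    (1-pre_share)*window)``. At recording edges the slice is truncated,
    zero-padded back to nominal length (sensor channels; attitude and
    elevation are edge-replicated since a zero quaternion is not a
    rotation) and flagged as padded.
    """
    if window_s <= 0:
        raise SpottingError("window size must be positive")
    if not 0.0 <= pre_share <= 1.0:
        raise SpottingError("pre_share must lie in [0, 1]")
    n = len(rec)
    if not 0 <= event.index < n:
        raise SpottingError("detection event lies outside the recording")
    m = int(round(window_s * rec.fs))
    pre = int(round(pre_share * window_s * rec.fs))
    start = event.index - pre
    stop = start + m
    lo, hi = max(start, 0), min(stop, n)
    pad_left, pad_right = lo - start, stop - hi

    def pad(arr, fill_edge):
        sl = arr[lo:hi]
        if pad_left == 0 and pad_right == 0:
            return sl.copy()
        width = ((pad_left, pad_right),) + ((0, 0),) * (arr.ndim - 1)
        mode = "edge" if fill_edge else "constant"
        return np.pad(sl, width, mode=mode)

    return Segment(
        t0=(start) / rec.fs,
        fs=rec.fs,
        accel=pad(rec.accel, False),
        gyro=pad(rec.gyro, False),
        mag=pad(rec.mag, False),
        quat=pad(orient.quat, True),
        theta=pad(orient.theta, True),
        trigger_offset=event.index - start,
        padded=pad_left > 0 or pad_right > 0,
        meta={"trigger_time": event.time},
    )


def spot_and_extract(rec: ImuRecording, orient: OrientationSeries,
                     rule: DetectionRule | None = None,
                     window_s: float = 2.0, pre_share: float = 0.4) -> list[Segment]:
    """Convenience: run :func:`spot` then :func:`extract` for every event."""
    events = spot(orient.theta, orient.rate_mag, rec.fs, rule)
    return [extract(rec, orient, ev, window_s, pre_share) for ev in events]
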