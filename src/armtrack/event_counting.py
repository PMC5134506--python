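"""Histogram with a debounced event counter for scalar sensor series.

A classic histogram of an elevation or angular-rate series tells how much
*time* the arm spent in each state, but not how many *separate times* a
state was visited: one overhead reach at 50 Hz deposits dozens of samples
in the high-elevation bins. The event counter fixes this with a refractory
rule -- a new event is counted in a bin only if the bin was last occupied
more than one second ago. Sustained occupancy of a bin therefore counts
once, and re-entries within the refractory window are absorbed, because
the last-occupancy marker is refreshed on *every* sample assigned to the
bin, not only on counted events.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


class EventCountError(Exception):
    pass


@dataclass
class EventHistogram:
    """Paired per-bin sample counts and debounced event counts.

    ``histogram[b]`` is the number of samples assigned to bin ``b`` (a
    classic histogram over nearest bin centers); ``event_count[b]`` is the
    number of visits to ``b`` separated by more than ``event_spread``
    samples (= 1 s at the recording's sampling rate).
    """

    bin_centers: np.ndarray
    histogram: np.ndarray
    event_count: np.ndarray
    event_spread: int

    def __post_init__(self) -> None:
        assert self.histogram.shape == self.bin_centers.shape == self.event_count.shape
        assert np.all(self.event_count <= self.histogram)


def nearest_bin(value: float, bin_centers) -> int:
    """Index of the bin center closest to ``value``; ties go to the
    smallest index (stable, platform-independent)."""
    centers = np.asarray(bin_centers, dtype=float)
    if centers.size == 0:
        raise EventCountError("at least one bin center is required")
    return int(np.argmin(np.abs(centers - value)))


def hist_and_count(data, bin_centers, fs: float) -> EventHistogram:
    """Histogram + debounced event count of a scalar series.

    Each sample is assigned to its nearest bin center (ties to the lower
    index). The histogram counts every sample. The event counter for a bin
    increments only when the bin's previous occupancy lies more than
    ``event_spread = 1 s * fs`` samples in the past; the occupancy marker
    is refreshed on every assignment. The first occupancy of a bin always
    counts.
    """
    x = np.asarray(data, dtype=float).ravel()
    centers = np.asarray(bin_centers, dtype=float).ravel()
    if centers.size == 0:
        raise EventCountError("at least one bin center is required")
    if x.size == 0:
        raise EventCountError("data must contain at least one sample")
    if fs <= 0:
        raise EventCountError("sampling frequency must be positive")
    spread = int(round(1.0 * fs))

    # nearest-center assignment; np.argmin keeps the lowest index on ties
    assigned = np.argmin(np.abs(x[:, None] - centers[None, :]), axis=1)

    histogram = np.bincount(assigned, minlength=centers.size)
    event_count = np.zeros(centers.size, dtype=int)
    for b in range(centers.size):
        idx = np.flatnonzero(assigned == b)
        if idx.size:
            # an assignment starts a new event iff the previous assignment
            # of this bin is more than `spread` samples in the past
            event_count[b] = 1 + int(np.count_nonzero(np.diff(idx) > spread))
    return EventHistogram(
        bin_centers=centers,
        histogram=histogram,
        event_count=event_count,
        event_spread=spread,
    )


def default_theta_bins() -> np.ndarray:
    """20-degree-wide elevation bins, centers 10..170 deg."""
    return np.arange(10.0, 180.0, 20.0)


def default_rate_bins(max_rate: float = 2500.0) -> np.ndarray:
    """150 deg/s-wide angular-rate bins, centers 75..~max_rate deg/s."""
    return np.arange(75.0, max_rate, 150.0)


def elevation_event_report(rec, cfg=None, bins_theta=None, bins_rate=None):
    """Event histograms of filtered elevation and angular-rate magnitude.

    Runs the fusion filter over ``rec`` and applies :func:`hist_and_count`
    to the filtered elevation series and to the gyro-magnitude series.
    Returns ``(theta_hist, rate_hist)``.
    """
    from .orientation import estimate_series

    series = estimate_series(rec, cfg)
    theta_bins = default_theta_bins() if bins_theta is None else bins_theta
    rate_bins = default_rate_bins() if bins_rate is None else bins_rate
    theta_hist = hist_and_count(series.theta, theta_bins, rec.fs)
    rate_hist = hist_and_count(series.rate_mag, rate_bins, rec.fs)
    return theta_hist, rate_hist
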