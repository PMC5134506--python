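"""The 81-value segment feature vector and forward sequential selection.

Each extracted segment is summarised by 81 named scalars:

* 36 order statistics -- min, max, range and median of the acceleration,
  rotation rate and per-axis elevation relative to gravity, for all three
  device axes;
* 3 values of the rotation-rate vector at the sample of maximum arm
  elevation;
* 3 components of the unit rotation axis at the sample of maximum
  rotation-rate magnitude;
* 39 mean FFT magnitudes of the rotation rate in fixed frequency bands
  (13 bands per axis at a 50 Hz sampling rate).

The band set per axis is an 11-band tiling of (0, 25] Hz --
0-0.5, 0.5-1.5, 1.5-2.5, 2.5-5, 5-7.5, 7.5-10, 10-12.5, 12.5-15,
15-17.5, 17.5-20, 20-25 Hz -- plus the two broad aggregates 5-10 and
10-25 Hz, so that every band used by the reduced 8-feature classifier is
available as a single named feature.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .spotting import Segment


class FeatureError(Exception):
    pass


AXES = ("x", "y", "z")
STATS = ("min", "max", "range", "median")

#: exact tiling of (0, 25] Hz (11 bands) ...
FINE_BANDS = (
    (0.0, 0.5), (0.5, 1.5), (1.5, 2.5), (2.5, 5.0), (5.0, 7.5), (7.5, 10.0),
    (10.0, 12.5), (12.5, 15.0), (15.0, 17.5), (17.5, 20.0), (20.0, 25.0),
)
#: ... plus broad aggregates needed as single features by the reduced model
AGGREGATE_BANDS = ((5.0, 10.0), (10.0, 25.0))
BANDS = FINE_BANDS + AGGREGATE_BANDS


def _fmt(f: float) -> str:
    return f"{f:g}".replace(".", "p")


def band_name(axis: str, lo: float, hi: float) -> str:
    return f"fft_g{axis}_{_fmt(lo)}_{_fmt(hi)}"


def _build_registry() -> tuple:
    names = []
    for sig in ("acc", "gyr", "elev"):
        for axis in AXES:
            for stat in STATS:
                names.append(f"{sig}_{axis}_{stat}")
    names += [f"gyr_at_max_elev_{a}" for a in AXES]
    names += [f"rot_axis_at_max_rate_{a}" for a in AXES]
    for axis in AXES:
        for lo, hi in BANDS:
            names.append(band_name(axis, lo, hi))
    return tuple(names)


#: stable ordering of all 81 features
FEATURE_NAMES = _build_registry()
assert len(FEATURE_NAMES) == 81

#: the 8 features used by the reduced classifier: rotation-axis x and z
#: components at peak rate, the x-axis range of motion relative to gravity,
#: and five rotation-rate band means.
SELECTED_FEATURES = (
    "rot_axis_at_max_rate_x",
    "rot_axis_at_max_rate_z",
    "elev_x_range",
    band_name("y", 5.0, 10.0),
    band_name("y", 10.0, 25.0),
    band_name("z", 0.0, 0.5),
    band_name("z", 2.5, 5.0),
    band_name("x", 0.5, 1.5),
)


def _stats(name: str, arr: np.ndarray, out: dict) -> None:
    for axis_i, axis in enumerate(AXES):
        col = arr[:, axis_i]
        out[f"{name}_{axis}_min"] = float(col.min())
        out[f"{name}_{axis}_max"] = float(col.max())
        out[f"{name}_{axis}_range"] = float(col.max() - col.min())
        out[f"{name}_{axis}_median"] = float(np.median(col))


def band_means(signal: np.ndarray, fs: float) -> dict:
    """Mean one-sided FFT magnitude of each band for one gyro axis.

    Magnitudes are ``|rfft| / n`` (length-normalised, unwindowed); a band
    mean averages the bins whose center frequency falls in ``[lo, hi)``.
    Circular time shifts leave every value unchanged.
    """
    n = signal.shape[0]
    mags = np.abs(np.fft.rfft(signal)) / n
    freqs = np.fft.rfftfreq(n, 1.0 / fs)
    out = {}
    for lo, hi in BANDS:
        sel = (freqs >= lo) & (freqs < hi)
        out[(lo, hi)] = float(mags[sel].mean()) if sel.any() else 0.0
    return out


def compute_features(seg: Segment) -> pd.Series:
    """Deterministic 81-value feature vector of a segment.

    Per-axis elevation relative to gravity is the angle between each
    device axis and nadir, taken from the fused attitude track. The
    rotation axis at peak rate is the unit-normalised gyro vector there,
    encoded as (0, 0, 0) when the peak rate is below 1 deg/s (axis
    undefined at rest).
    """
    if len(seg) < 2:
        raise FeatureError("segment must contain at least 2 samples")
    from .orientation import axis_elevations

    out: dict = {}
    elev = axis_elevations(seg.quat)
    _stats("acc", seg.accel, out)
    _stats("gyr", seg.gyro, out)
    _stats("elev", elev, out)

    rate = np.linalg.norm(seg.gyro, axis=1)
    i_elev = int(np.argmax(elev[:, 0]))
    for axis_i, axis in enumerate(AXES):
        out[f"gyr_at_max_elev_{axis}"] = float(seg.gyro[i_elev, axis_i])

    i_rate = int(np.argmax(rate))
    if rate[i_rate] < 1.0:
        axis_vec = np.zeros(3)
    else:
        axis_vec = seg.gyro[i_rate] / rate[i_rate]
    for axis_i, axis in enumerate(AXES):
        out[f"rot_axis_at_max_rate_{axis}"] = float(axis_vec[axis_i])

    for axis_i, axis in enumerate(AXES):
        bm = band_means(seg.gyro[:, axis_i], seg.fs)
        for (lo, hi), val in bm.items():
            out[band_name(axis, lo, hi)] = val

    vec = pd.Series(out).reindex(list(FEATURE_NAMES))
    if vec.isna().any() or not np.all(np.isfinite(vec.to_numpy())):
        raise FeatureError("non-finite feature values")
    return vec


def feature_table(segments) -> pd.DataFrame:
    """Stack feature vectors of several segments into a DataFrame."""
    return pd.DataFrame([compute_features(s) for s in segments])


# ---------------------------------------------------------------------------
# forward sequential feature selection
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SelectedFeatureSet:
    """Ordered result of a greedy wrapper selection."""

    names: tuple

    def __len__(self) -> int:
        return len(self.names)


def forward_select(X: pd.DataFrame, y, k: int = 8, seed: int = 0,
                   estimator=None, cv: int = 3) -> SelectedFeatureSet:
    """Greedy wrapper selection of up to ``k`` features.

    Features are added one at a time, each time picking the candidate
    that maximises stratified cross-validated accuracy of the stage-2
    classifier; selection stops early when no candidate improves the
    score. Deterministic for a fixed ``seed``.
    """
    from sklearn.ensemble import BaggingClassifier
    from sklearn.model_selection import StratifiedKFold, cross_val_score
    from sklearn.tree import DecisionTreeClassifier

    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise FeatureError("forward selection needs at least two classes")
    if k < 0 or k > X.shape[1]:
        raise FeatureError(f"k must lie in [0, {X.shape[1]}]")
    if k == 0:
        return SelectedFeatureSet(names=())
    if estimator is None:
        estimator = BaggingClassifier(
            DecisionTreeClassifier(random_state=seed),
            n_estimators=25,
            random_state=seed,
        )
    splitter = StratifiedKFold(n_splits=cv, shuffle=True, random_state=seed)

    remaining = list(X.columns)
    chosen: list = []
    best_score = -np.inf
    while remaining and len(chosen) < k:
        scores = []
        for name in remaining:
            cols = chosen + [name]
            s = cross_val_score(estimator, X[cols].to_numpy(), y, cv=splitter).mean()
            scores.append(s)
        i = int(np.argmax(scores))
        if scores[i] <= best_score:
            break  # no candidate improves prediction
        best_score = scores[i]
        chosen.append(remaining.pop(i))
    return SelectedFeatureSet(names=tuple(chosen))
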