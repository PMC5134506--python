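"""Evaluation statistics: confusion matrices, accuracy, Bland-Altman.

Per-event classification quality is summarised by a 3x3 confusion matrix
over (Throw, Serve, Neither), rows true, columns predicted, and its
accuracy (trace over total, percent). Per-session count agreement with a
gold-standard observer uses Bland-Altman analysis of the paired
differences d = algorithm - observed: the mean difference (bias), its 95%
t-based confidence interval, the classical limits of agreement
(mean +/- 1.96 sd) and the Pearson correlation of the two count vectors.
With the algorithm-minus-observed sign convention, systematic
undercounting shows up as a negative mean difference.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sstats
from sklearn.metrics import confusion_matrix as _sk_confusion

from .classification import CLASSES


class AgreementError(Exception):
    pass


@dataclass
class ConfusionMatrix:
    """Integer counts, rows = true class, columns = predicted class."""

    counts: np.ndarray
    labels: tuple = CLASSES

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        k = len(self.labels)
        if self.counts.shape != (k, k):
            raise AgreementError(f"expected a {k}x{k} matrix, got {self.counts.shape}")
        if np.any(self.counts < 0):
            raise AgreementError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def row_fraction(self, label: str) -> float:
        """Diagonal count over row total for one true class, percent."""
        i = self.labels.index(label)
        row = self.counts[i].sum()
        if row == 0:
            raise AgreementError(f"no true events of class {label!r}")
        return 100.0 * self.counts[i, i] / row


@dataclass
class AgreementStats:
    """Bland-Altman summary of paired per-session counts."""

    n: int
    mean_diff: float
    ci_low: float
    ci_high: float
    loa_low: float
    loa_high: float
    sd_diff: float
    pearson_r: float        # nan when either vector is constant
    degenerate: bool        # constant differences: CI/limits collapse


def confusion(true_labels, pred_labels, labels: tuple = CLASSES) -> ConfusionMatrix:
    """Count (true, predicted) pairs into a confusion matrix."""
    true_labels = list(true_labels)
    pred_labels = list(pred_labels)
    if len(true_labels) != len(pred_labels):
        raise AgreementError("label vectors must have equal length")
    unknown = set(true_labels) | set(pred_labels)
    unknown -= set(labels)
    if unknown:
        raise AgreementError(f"unknown labels {sorted(unknown)}")
    counts = _sk_confusion(true_labels, pred_labels, labels=list(labels))
    return ConfusionMatrix(counts=counts, labels=tuple(labels))


def accuracy(cm: ConfusionMatrix) -> float:
    """Percent accuracy: 100 x (sum of diagonal elements) / (overall sum)."""
    if cm.total == 0:
        raise AgreementError("accuracy undefined for an empty matrix")
    return 100.0 * float(np.trace(cm.counts)) / cm.total


def bland_altman(algorithm_counts, observed_counts) -> AgreementStats:
    """Agreement between algorithm and observed per-session counts.

    Differences are ``algorithm - observed``. The CI of the mean uses the
    t distribution with n-1 degrees of freedom; limits of agreement are
    mean +/- 1.96 sd. Pearson r is reported as nan (and the result flagged
    degenerate where applicable) when a correlation is undefined.
    """
    a = np.asarray(algorithm_counts, dtype=float)
    b = np.asarray(observed_counts, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise AgreementError("count vectors must be equal-length 1-D")
    n = a.size
    if n < 2:
        raise AgreementError("at least 2 paired sessions are required")
    d = a - b
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    degenerate = sd == 0.0
    if degenerate:
        ci = (mean, mean)
        loa = (mean, mean)
    else:
        half = sd / np.sqrt(n) * sstats.t.ppf(0.975, n - 1)
        ci = (mean - half, mean + half)
        loa = (mean - 1.96 * sd, mean + 1.96 * sd)
    if a.std() == 0.0 or b.std() == 0.0:
        r = float("nan")
    else:
        r = float(sstats.pearsonr(a, b).statistic)
    return AgreementStats(
        n=n,
        mean_diff=mean,
        ci_low=float(ci[0]),
        ci_high=float(ci[1]),
        loa_low=float(loa[0]),
        loa_high=float(loa[1]),
        sd_diff=sd,
        pearson_r=r,
        degenerate=degenerate,
    )


def bland_altman_plot(algorithm_counts, observed_counts, path) -> None:
    """Write a Bland-Altman scatter (mean vs difference) to ``path``."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    a = np.asarray(algorithm_counts, dtype=float)
    b = np.asarray(observed_counts, dtype=float)
    st = bland_altman(a, b)
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter((a + b) / 2.0, a - b, alpha=0.7)
    ax.axhline(st.mean_diff, color="k", lw=1, label=f"mean {st.mean_diff:.2f}")
    for y in (st.loa_low, st.loa_high):
        ax.axhline(y, color="k", lw=1, ls="--")
    ax.set_xlabel("mean of counts")
    ax.set_ylabel("algorithm - observed")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
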