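"""Stage-2 bagged decision-tree classifier with null-class rejection.

A bootstrap-aggregated ensemble of 160 unpruned decision trees assigns
each extracted segment to a gesture class. Class scores are per-tree vote
fractions; a segment is accepted as a throw or a serve only if the winning
sport class carries at least 60% of the votes, otherwise it falls into the
catch-all "Neither" class. The ensemble is trained on a stratified 40%
split and evaluated on the remaining 60%.
"""

from __future__ import annotations

import pickle
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.ensemble import BaggingClassifier
from sklearn.model_selection import train_test_split
from sklearn.tree import DecisionTreeClassifier

from .features import SELECTED_FEATURES, compute_features
from .imu import ImuRecording
from .orientation import FusionConfig, estimate_series
from .spotting import DetectionRule, extract, spot

#: the three gesture classes, in canonical order
THROW = "Throw"
SERVE = "Serve"
NEITHER = "Neither"
CLASSES = (THROW, SERVE, NEITHER)

#: sport classes that are counted (Neither is reported but never counted)
SPORT_CLASSES = (THROW, SERVE)


class ClassificationError(Exception):
    pass


@dataclass
class TrainConfig:
    n_trees: int = 160
    train_frac: float = 0.4
    score_threshold: float = 0.60
    seed: int = 0


@dataclass
class EnsembleModel:
    """Trained bagged-tree ensemble plus the feature subset it expects."""

    clf: BaggingClassifier
    feature_names: tuple
    classes: tuple
    config: TrainConfig
    meta: dict = field(default_factory=dict)

    @property
    def n_trees(self) -> int:
        return len(self.clf.estimators_)


@dataclass
class PipelineConfig:
    """End-to-end settings: fusion -> spotting -> windowing -> decision."""

    fusion: FusionConfig = field(default_factory=FusionConfig)
    rule: DetectionRule = field(default_factory=DetectionRule)
    window_s: float = 2.0
    pre_share: float = 0.4
    score_threshold: float = 0.60


@dataclass
class PipelineResult:
    events: list          # (time_s, predicted class, winning sport score)
    counts: dict          # per sport class counted events


def train(X: pd.DataFrame, y, cfg: TrainConfig | None = None):
    """Fit the ensemble on a stratified ``train_frac`` split.

    Returns ``(model, test_index)`` where ``test_index`` indexes the
    held-out rows of ``X`` (the remaining 60% used for testing). The fit
    is bit-stable for a fixed seed.
    """
    cfg = cfg or TrainConfig()
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        raise ClassificationError("training requires at least two classes")
    if len(y) < 10:
        raise ClassificationError("training requires at least 10 samples")
    if counts.min() < 2:
        small = classes[counts.argmin()]
        raise ClassificationError(f"class {small!r} has fewer than 2 samples")
    idx = np.arange(len(y))
    train_idx, test_idx = train_test_split(
        idx, train_size=cfg.train_frac, stratify=y, random_state=cfg.seed
    )
    clf = BaggingClassifier(
        DecisionTreeClassifier(random_state=cfg.seed),
        n_estimators=cfg.n_trees,
        bootstrap=True,
        random_state=cfg.seed,
    )
    clf.fit(X.iloc[train_idx].to_numpy(), y[train_idx])
    model = EnsembleModel(
        clf=clf,
        feature_names=tuple(X.columns),
        classes=tuple(clf.classes_.tolist()),
        config=cfg,
        meta={"n_train": len(train_idx), "n_test": len(test_idx)},
    )
    return model, test_idx


def _tree_votes(model: EnsembleModel, X: np.ndarray) -> np.ndarray:
    """Per-class vote fractions across the trees, shape (n, n_classes)."""
    clf = model.clf
    n = X.shape[0]
    agg = np.zeros((n, len(clf.classes_)))
    rows = np.arange(n)
    for est, feats in zip(clf.estimators_, clf.estimators_features_):
        pred = est.predict(X[:, feats])
        # base estimators are fit on label-encoded targets (0..k-1)
        agg[rows, pred.astype(int)] += 1.0
    return agg / len(clf.estimators_)


def predict_scores(model: EnsembleModel, fv) -> dict:
    """Class scores (tree vote fractions, summing to 1) for one segment.

    ``fv`` may be a feature ``Series`` or mapping; it must contain every
    feature the model was trained on.
    """
    if isinstance(fv, pd.Series):
        fv = fv.to_dict()
    missing = [f for f in model.feature_names if f not in fv]
    if missing:
        raise ClassificationError(f"feature vector is missing {missing[:5]}")
    x = np.array([[fv[f] for f in model.feature_names]])
    votes = _tree_votes(model, x)[0]
    return {cls: float(v) for cls, v in zip(model.clf.classes_, votes)}


def decide(scores: dict, threshold: float = 0.60) -> str:
    """Accept the best-fitting sport class or reject to ``Neither``.

    The winning sport class must carry at least ``threshold`` of the
    votes (inclusive comparison); anything else is ``Neither``.
    """
    sport = {c: scores.get(c, 0.0) for c in SPORT_CLASSES}
    best = max(sport, key=sport.get)
    return best if sport[best] >= threshold else NEITHER


def save_model(model: EnsembleModel, path: str | Path) -> None:
    """Persist as a single binary artifact (predictions reload identically)."""
    with open(path, "wb") as fh:
        pickle.dump(model, fh)


def load_model(path: str | Path) -> EnsembleModel:
    with open(path, "rb") as fh:
        model = pickle.load(fh)
    if not isinstance(model, EnsembleModel):
        raise ClassificationError(f"{path} does not contain an EnsembleModel")
    return model


def run_pipeline(rec: ImuRecording, model: EnsembleModel,
                 cfg: PipelineConfig | None = None) -> PipelineResult:
    """Causal end-to-end run: fuse, spot, extract, featurise, score, decide.

    Returns every detection with its decided class; only Throw and Serve
    decisions enter the counts.
    """
    cfg = cfg or PipelineConfig()
    orient = estimate_series(rec, cfg.fusion)
    events = spot(orient.theta, orient.rate_mag, rec.fs, cfg.rule)
    out = []
    counts = {c: 0 for c in SPORT_CLASSES}
    for ev in events:
        seg = extract(rec, orient, ev, cfg.window_s, cfg.pre_share)
        fv = compute_features(seg)
        scores = predict_scores(model, fv)
        cls = decide(scores, cfg.score_threshold)
        best_sport = max(scores.get(c, 0.0) for c in SPORT_CLASSES)
        out.append((ev.time, cls, best_sport))
        if cls in counts:
            counts[cls] += 1
    return PipelineResult(events=out, counts=counts)


def default_feature_subset() -> tuple:
    """The reduced 8-feature subset used by the default model."""
    return SELECTED_FEATURES
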