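"""Ensemble training, vote scores, null-class gate and the full pipeline."""

import numpy as np
import pandas as pd
import pytest

from armtrack import synthetic as syn
from armtrack.classification import (
    NEITHER,
    ClassificationError,
    TrainConfig,
    _tree_votes,
    decide,
    load_model,
    predict_scores,
    run_pipeline,
    save_model,
    train,
)
from conftest import make_recording


def _separable_data(rng, n=80):
    X = pd.DataFrame(rng.normal(size=(n, 4)), columns=list("abcd"))
    y = np.where(X["a"] > 0, "Throw", "Serve")
    X["a"] = X["a"] + np.where(X["a"] > 0, 2.0, -2.0)  # widen the margin
    return X, y


class TestTrain:
    def test_separable_data_perfect_held_out_accuracy(self, rng):
        X, y = _separable_data(rng)
        model, test_idx = train(X, y, TrainConfig(n_trees=40, seed=0))
        votes = _tree_votes(model, X.iloc[test_idx].to_numpy())
        pred = np.asarray(model.clf.classes_)[votes.argmax(axis=1)]
        assert (pred == y[test_idx]).all()

    def test_split_is_stratified_40_60(self, rng):
        X, y = _separable_data(rng, n=100)
        model, test_idx = train(X, y, TrainConfig(seed=3))
        assert len(test_idx) == 60
        assert model.meta["n_train"] == 40

    def test_same_seed_is_bit_stable(self, rng):
        X, y = _separable_data(rng)
        m1, t1 = train(X, y, TrainConfig(n_trees=30, seed=5))
        m2, t2 = train(X, y, TrainConfig(n_trees=30, seed=5))
        np.testing.assert_array_equal(t1, t2)
        v1 = _tree_votes(m1, X.to_numpy())
        v2 = _tree_votes(m2, X.to_numpy())
        np.testing.assert_array_equal(v1, v2)

    def test_single_class_rejected(self, rng):
        X, _ = _separable_data(rng)
        with pytest.raises(ClassificationError):
            train(X, np.array(["Throw"] * len(X)), TrainConfig())

    def test_tiny_class_rejected(self, rng):
        X, y = _separable_data(rng, n=20)
        y = y.copy()
        y[:] = "Throw"
        y[0] = "Serve"
        with pytest.raises(ClassificationError, match="fewer than 2"):
            train(X, y, TrainConfig())


class TestScoresAndDecision:
    def test_unanimous_trees_score_one(self, rng):
        X, y = _separable_data(rng)
        model, _ = train(X, y, TrainConfig(n_trees=40, seed=0))
        fv = X.iloc[int(np.argmax(X["a"].to_numpy()))]
        scores = predict_scores(model, fv)
        assert scores["Throw"] == pytest.approx(1.0)

    def test_scores_are_vote_fractions_summing_to_one(self, rng):
        X, y = _separable_data(rng, n=60)
        # inject label noise so trees disagree
        y = y.copy()
        flip = rng.choice(len(y), size=12, replace=False)
        y[flip] = np.where(y[flip] == "Throw", "Serve", "Throw")
        model, _ = train(X, y, TrainConfig(n_trees=20, seed=1))
        probe = pd.DataFrame(rng.normal(size=(300, 4)), columns=list("abcd"))
        votes = _tree_votes(model, probe.to_numpy())
        np.testing.assert_allclose(votes.sum(axis=1), 1.0, atol=1e-9)
        # every score is a multiple of 1/n_trees (a pure vote fraction)
        np.testing.assert_allclose(
            np.round(votes * 20) / 20, votes, atol=1e-12
        )

    def test_missing_feature_rejected(self, rng):
        X, y = _separable_data(rng)
        model, _ = train(X, y, TrainConfig(n_trees=10, seed=0))
        with pytest.raises(ClassificationError, match="missing"):
            predict_scores(model, {"a": 1.0})

    @pytest.mark.parametrize(
        "scores, expected",
        [
            ({"Throw": 0.9, "Serve": 0.1}, "Throw"),
            ({"Throw": 0.55, "Serve": 0.45}, NEITHER),   # max below the gate
            ({"Throw": 0.60, "Serve": 0.40}, "Throw"),   # boundary is inclusive
            ({"Throw": 0.10, "Serve": 0.90}, "Serve"),
        ],
    )
    def test_posterior_gate(self, scores, expected):
        assert decide(scores, threshold=0.60) == expected


class TestPersistence:
    def test_serialized_model_predicts_identically(self, rng, tmp_path):
        X, y = _separable_data(rng)
        model, _ = train(X, y, TrainConfig(n_trees=25, seed=2))
        p = tmp_path / "model.pkl"
        save_model(model, p)
        back = load_model(p)
        np.testing.assert_array_equal(
            _tree_votes(model, X.to_numpy()), _tree_votes(back, X.to_numpy())
        )
        assert back.feature_names == model.feature_names

    def test_wrong_artifact_rejected(self, tmp_path):
        p = tmp_path / "junk.pkl"
        import pickle

        p.write_bytes(pickle.dumps({"not": "a model"}))
        with pytest.raises(ClassificationError):
            load_model(p)


class TestPipeline:
    def test_quiet_recording_yields_zero_counts(self, rng, recovery):
        model, _ = recovery
        rec = make_recording(n=150)  # 3 s of rest
        result = run_pipeline(rec, model)
        assert result.counts == {"Throw": 0, "Serve": 0}
        assert result.events == []

    def test_exercise_session_yields_zero_sport_counts(self, recovery):
        model, _ = recovery
        rec, _ = syn.generate_session(syn.exercises_only_script(seed=17, reps=3))
        result = run_pipeline(rec, model)
        assert result.counts == {"Throw": 0, "Serve": 0}

    def test_sports_counts_match_ground_truth(self, recovery, sports_session):
        model, _ = recovery
        rec, truth = sports_session
        result = run_pipeline(rec, model)
        assert abs(result.counts["Throw"] - truth.sport_counts["Throw"]) <= 1
        assert abs(result.counts["Serve"] - truth.sport_counts["Serve"]) <= 1
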