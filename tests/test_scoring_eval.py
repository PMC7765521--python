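"""Classifier training, segment metrics, channel scoring and the trapezoid AUC."""

import itertools

import numpy as np
import pandas as pd
import pytest

from sozloc import (
    ConfigurationError,
    channel_auc,
    channel_scores,
    score_segments,
    segment_metrics,
    train_balanced,
    train_classifier,
)

import oracles


def separable_data(rng, n=60, cols=4, gap=4.0):
    y = np.array([0, 1] * (n // 2))
    X = rng.standard_normal((n, cols)) + gap * y[:, None]
    return X, y


class TestTrainClassifier:
    @pytest.mark.parametrize("kind", ["gbdt", "svm_rbf"])
    def test_separable_training_set_is_learned(self, kind, rng):
        X, y = separable_data(rng)
        scorer = train_classifier(X, y, kind=kind, seed=0)
        proba = scorer.predict_proba(X)
        assert ((proba >= 0.5).astype(int) == y).mean() == 1.0
        assert (proba >= 0).all() and (proba <= 1).all()

    def test_same_seed_identical_predictions(self, rng):
        X, y = separable_data(rng, gap=1.0)
        a = train_classifier(X, y, seed=3).predict_proba(X)
        b = train_classifier(X, y, seed=3).predict_proba(X)
        np.testing.assert_array_equal(a, b)

    def test_single_class_rejected(self, rng):
        X = rng.standard_normal((10, 2))
        with pytest.raises(ValueError):
            train_classifier(X, np.zeros(10, dtype=int))

    def test_permuted_labels_give_chance_auc(self, rng):
        from sklearn.metrics import roc_auc_score

        X, _ = separable_data(rng, n=200, gap=0.0)
        y = (rng.random(200) < 0.5).astype(int)
        scorer = train_classifier(X[:150], y[:150], seed=0)
        auc = roc_auc_score(y[150:], scorer.predict_proba(X[150:]))
        assert 0.25 <= auc <= 0.75  # no signal to learn

    def test_unknown_kind(self, rng):
        X, y = separable_data(rng)
        with pytest.raises(ConfigurationError):
            train_classifier(X, y, kind="forest")

    def test_layout_mismatch_rejected(self, rng):
        X, y = separable_data(rng, cols=4)
        scorer = train_classifier(X, y, seed=0)
        with pytest.raises(ValueError, match="layout"):
            scorer.predict_proba(rng.standard_normal((5, 3)))

    def test_train_balanced_handles_imbalance(self, rng):
        y = np.array([1] * 6 + [0] * 54)
        X = rng.standard_normal((60, 3)) + 3.0 * y[:, None]
        scorer = train_balanced(X, y, seed=0)
        assert (scorer.predict(X) == y).mean() >= 0.95


class TestSegmentMetrics:
    def test_worked_example(self):
        pred = [1] * 8 + [0] * 2 + [0] * 9 + [1] * 1
        labels = [1] * 10 + [0] * 10
        m = segment_metrics(pred, labels)
        assert (m.tp, m.fn, m.tn, m.fp) == (8, 2, 9, 1)
        assert m.sensitivity == pytest.approx(80.0)
        assert m.specificity == pytest.approx(90.0)
        assert m.f1 == pytest.approx(8 / 9.5)

    def test_perfect_prediction(self):
        m = segment_metrics([1, 0, 1], [1, 0, 1])
        assert (m.sensitivity, m.specificity, m.f1) == (100.0, 100.0, 1.0)

    def test_no_true_positive(self):
        m = segment_metrics([0, 0], [1, 1])
        assert m.sensitivity == 0.0 and m.f1 == 0.0

    def test_undefined_metrics_reported_missing(self):
        m = segment_metrics([0, 1], [0, 1])  # only one positive, one negative
        assert segment_metrics([0], [0]).sensitivity is None
        assert segment_metrics([1], [1]).specificity is None
        assert m.f1 == 1.0

    def test_count_identities(self, rng):
        pred = (rng.random(50) < 0.5).astype(int)
        labels = (rng.random(50) < 0.3).astype(int)
        m = segment_metrics(pred, labels)
        assert m.tp + m.fn == labels.sum()
        assert m.tn + m.fp == (1 - labels).sum()
        assert 0.0 <= (m.f1 or 0.0) <= 1.0

    def test_adding_correct_positive_never_hurts(self, rng):
        pred = list((rng.random(30) < 0.5).astype(int))
        labels = list((rng.random(30) < 0.5).astype(int))
        before = segment_metrics(pred, labels)
        after = segment_metrics(pred + [1], labels + [1])
        assert after.sensitivity >= before.sensitivity
        assert (after.f1 or 0) >= (before.f1 or 0)


class TestChannelScores:
    def test_mean_and_rank(self):
        table = pd.DataFrame(
            {
                "channel": ["A", "A", "B", "B", "C"],
                "score": [0.2, 0.4, 0.9, 0.7, 0.5],
                "label": [0, 0, 1, 1, 0],
            }
        )
        out = channel_scores(table)
        row = out.set_index("channel")
        assert row.loc["A", "mean_score"] == pytest.approx(0.3)
        assert row.loc["B", "mean_score"] == pytest.approx(0.8)
        assert row.loc["C", "mean_score"] == pytest.approx(0.5)
        assert list(out.sort_values("rank")["channel"]) == ["B", "C", "A"]

    def test_single_segment_channel(self):
        table = pd.DataFrame({"channel": ["X"], "score": [0.42], "label": [1]})
        assert channel_scores(table)["mean_score"].iloc[0] == pytest.approx(0.42)

    def test_ranking_matches_bruteforce(self, rng):
        names = [f"C{i}" for i in range(10)]
        table = pd.DataFrame(
            {
                "channel": np.repeat(names, 5),
                "score": rng.random(50),
                "label": np.repeat((rng.random(10) < 0.4).astype(int), 5),
            }
        )
        out = channel_scores(table)
        brute = sorted(names, key=lambda c: -table.loc[table.channel == c, "score"].mean())
        assert list(out.sort_values("rank")["channel"]) == brute

    def test_score_segments_contract(self, rng):
        X, y = separable_data(rng, n=20)
        scorer = train_classifier(X, y, seed=0)
        frame = score_segments(scorer, X, ["ch"] * 20, range(20), y)
        assert set(frame.columns) == {"channel", "segment_index", "score", "label"}
        assert frame.score.between(0, 1).all()
        # identical rows get identical scores
        twice = score_segments(scorer, np.vstack([X[:1], X[:1]]), ["a", "b"], [0, 0])
        assert twice.score.iloc[0] == twice.score.iloc[1]


def _table(scores, labels):
    return pd.DataFrame({"mean_score": scores, "label": labels})


class TestChannelAUC:
    def test_perfect_separation(self):
        assert channel_auc(_table([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])) == 1.0

    def test_inverted_separation(self):
        assert channel_auc(_table([0.1, 0.9], [1, 0])) == 0.0

    def test_all_equal_scores(self):
        assert channel_auc(_table([0.5] * 6, [1, 1, 0, 0, 0, 0])) == pytest.approx(0.5)

    def test_single_class_rejected(self):
        with pytest.raises(ConfigurationError):
            channel_auc(_table([0.4, 0.6], [1, 1]))

    def test_matches_mannwhitney_on_all_small_configurations(self):
        """Trapezoid sweep == pair counting for every labelling of up to 8

        channels, with and without tied scores."""
        rng = np.random.default_rng(4)
        for n in range(2, 9):
            for labels in itertools.product([0, 1], repeat=n):
                if 0 < sum(labels) < n:
                    scores = np.round(rng.random(n), 1)  # coarse grid forces ties
                    got = channel_auc(_table(scores, list(labels)))
                    pos = scores[np.array(labels) == 1]
                    neg = scores[np.array(labels) == 0]
                    want = oracles.oracle_mannwhitney_auc(pos, neg)
                    assert got == pytest.approx(want, abs=1e-12)

    def test_matches_sklearn(self, rng):
        from sklearn.metrics import roc_auc_score

        scores = rng.random(12)
        labels = np.array([1] * 4 + [0] * 8)
        assert channel_auc(_table(scores, labels)) == pytest.approx(
            roc_auc_score(labels, scores)
        )
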