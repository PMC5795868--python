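"""Pattern classifier, majority vote, and evaluation utilities."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from semgrid import (
    PatternDataset,
    evaluate,
    majority_vote,
    nearest_centroid_baseline,
    predict,
    train_classifier,
)
from semgrid.classify import ClassifierModel, one_hot_encode


def toy_dataset(K=5, n_ch=8, n_per=30):
    rows = np.vstack([
        np.zeros((n_per, n_ch), dtype=int),
        np.full((n_per, n_ch), K - 1, dtype=int),
    ])
    labels = np.array(["open"] * n_per + ["close"] * n_per)
    return PatternDataset(rows, labels, K)


def test_one_hot_encoding_shape_and_content():
    enc = one_hot_encode(np.array([[0, 2], [1, 0]]), K=3)
    assert enc.shape == (2, 6)
    assert np.array_equal(enc[0], [1, 0, 0, 0, 0, 1])
    assert np.array_equal(enc[1], [0, 1, 0, 1, 0, 0])


class TestTraining:
    def test_separable_toy_reaches_full_accuracy(self):
        data = toy_dataset()
        model = train_classifier(data, epochs=50, seed=0)
        pred, _ = predict(model, data.rows)
        assert np.mean(pred == data.labels) == 1.0

    def test_seeded_determinism(self):
        data = toy_dataset()
        a = train_classifier(data, epochs=30, seed=5)
        b = train_classifier(data, epochs=30, seed=5)
        assert all(np.array_equal(x, y) for x, y in zip(a.coefs, b.coefs))
        assert all(np.array_equal(x, y) for x, y in zip(a.intercepts, b.intercepts))
        assert a.loss_curve == b.loss_curve

    def test_loss_curve_recorded_per_epoch(self):
        model = train_classifier(toy_dataset(), epochs=25, seed=0)
        assert len(model.loss_curve) <= 25
        assert all(np.isfinite(v) for v in model.loss_curve)

    def test_degenerate_data_rejected(self):
        rows = np.zeros((30, 4), dtype=int)
        with pytest.raises(ValueError, match="2 classes"):
            train_classifier(PatternDataset(rows, np.array(["a"] * 30), 2))
        labels = np.array(["a"] * 25 + ["b"] * 5)
        with pytest.raises(ValueError, match="10 examples"):
            train_classifier(PatternDataset(rows, labels, 2))

    def test_save_load_round_trip(self, tmp_path):
        model = train_classifier(toy_dataset(), epochs=20, seed=0)
        path = tmp_path / "clf.json"
        model.save(path)
        loaded = ClassifierModel.load(path)
        rows = toy_dataset().rows
        _, s1 = predict(model, rows)
        _, s2 = predict(loaded, rows)
        assert np.allclose(s1, s2, atol=1e-12)


class TestPredict:
    def test_scores_normalized(self):
        model = train_classifier(toy_dataset(), epochs=20, seed=0)
        rng = np.random.default_rng(0)
        rows = rng.integers(0, 5, size=(50, 8))
        _, scores = predict(model, rows)
        assert np.allclose(scores.sum(axis=1), 1.0, atol=1e-9)

    def test_shape_mismatch_rejected(self):
        model = train_classifier(toy_dataset(), epochs=10, seed=0)
        with pytest.raises(ValueError, match="channels"):
            predict(model, np.zeros((3, 5), dtype=int))

    def test_class_order_permutation_only_permutes_columns(self):
        rows = np.vstack([np.zeros((30, 4), int), np.ones((30, 4), int),
                          np.full((30, 4), 2, int)])
        labels = np.array(["a"] * 30 + ["b"] * 30 + ["c"] * 30)
        d1 = PatternDataset(rows, labels, 3, classes=["a", "b", "c"])
        d2 = PatternDataset(rows, labels, 3, classes=["c", "a", "b"])
        m1 = train_classifier(d1, epochs=30, seed=2)
        m2 = train_classifier(d2, epochs=30, seed=2)
        _, s1 = predict(m1, rows)
        _, s2 = predict(m2, rows)
        perm = [m2.classes.index(c) for c in m1.classes]
        assert np.allclose(s1, s2[:, perm], atol=1e-12)


def test_nearest_centroid_baseline_on_toy():
    data = toy_dataset()
    pred = nearest_centroid_baseline(data, data.rows)
    assert np.array_equal(pred, data.labels)


class TestMajorityVote:
    def test_two_of_three(self):
        out = majority_vote(np.array(["A", "A", "B"]), 3)
        assert out[-1] == "A"

    def test_constant_stream_unchanged(self):
        stream = np.array(["x"] * 25)
        assert np.array_equal(majority_vote(stream, 5), stream)

    def test_single_flip_removed(self):
        stream = np.array(["A"] * 10 + ["B"] + ["A"] * 10)
        out = majority_vote(stream, 5)
        assert np.all(out == "A")

    def test_tie_retains_previous_output(self):
        # spans are odd, so ties only arise in the shrunken startup
        # window: at t=1 the trailing window is (A, B) — keep output A
        out = majority_vote(np.array(["A", "B", "B"]), 3, classes=["B", "A"])
        assert out[0] == "A"
        assert out[1] == "A"
        assert out[2] == "B"

    def test_even_span_rejected(self):
        with pytest.raises(ValueError, match="odd"):
            majority_vote(np.array(["A"]), 4)

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(st.lists(st.sampled_from(["a", "b", "c"]), min_size=1, max_size=60),
           st.sampled_from([1, 3, 5, 9]))
    def test_never_introduces_absent_label(self, stream, span):
        stream = np.array(stream)
        out = majority_vote(stream, span)
        for t in range(len(stream)):
            window = set(stream[max(0, t - span + 1): t + 1])
            assert out[t] in window


class TestEvaluate:
    def test_perfect_prediction(self):
        truth = np.array(["a", "b", "c", "a"])
        rep = evaluate(truth, truth)
        assert rep.accuracy == 1.0
        assert np.trace(rep.confusion) == 4

    def test_constant_prediction_on_balanced_truth(self):
        truth = np.array(sum(([c] * 10 for c in "abcde"), []))
        pred = np.array(["a"] * 50)
        rep = evaluate(truth, pred)
        assert rep.accuracy == pytest.approx(0.2)

    def test_swapping_two_predictions_changes_at_most_two_cells(self):
        truth = np.array(["a", "a", "b", "b"])
        pred = np.array(["a", "b", "b", "b"])
        r1 = evaluate(truth, pred, classes=["a", "b"])
        swapped = pred.copy()
        swapped[[0, 1]] = swapped[[1, 0]]
        r2 = evaluate(truth, swapped, classes=["a", "b"])
        assert np.abs(r1.confusion - r2.confusion).sum() <= 2 * 2

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="lengths differ"):
            evaluate(np.array(["a"]), np.array(["a", "b"]))

    def test_label_outside_class_set_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            evaluate(np.array(["a"]), np.array(["z"]), classes=["a", "b"])
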