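"""Windowed RMS features: closed forms, window arithmetic, streaming."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from semgrid import (
    SignalRecord,
    StreamingRms,
    moving_average,
    sliding_rms,
    sliding_rms_streaming,
    total_activation,
)
from .conftest import sine_record

FS = 1000.0


def test_constant_signal_rms_is_exact():
    rec = SignalRecord(np.full((1000, 3), 3.0), FS)
    feats = sliding_rms(rec)
    assert np.all(feats.values == 3.0)


def test_bench_sine_rms_closed_form():
    """The 100 Hz, 1 mV verification tone over a 200 ms window (20 full
    periods) has RMS A/√2 = 707.1 μV."""
    rec = sine_record(100.0, 1000.0, FS, duration_s=1.0)
    feats = sliding_rms(rec, window_ms=200.0, step_ms=5.0)
    expected = 1000.0 / np.sqrt(2.0)
    assert np.all(np.abs(feats.values - expected) / expected <= 1e-3)


def test_window_count_example():
    rec = SignalRecord(np.zeros((1000, 1)), FS)
    feats = sliding_rms(rec, window_ms=200.0, step_ms=5.0)
    assert feats.n_windows == 161


@settings(derandomize=True, max_examples=200, deadline=None)
@given(
    w=st.integers(1, 50),
    s=st.integers(1, 20),
    extra=st.integers(0, 400),
)
def test_window_count_formula(w, s, extra):
    n = w + extra
    rec = SignalRecord(np.ones((n, 1)), FS)
    feats = sliding_rms(rec, window_ms=float(w), step_ms=float(s))
    assert feats.n_windows == (n - w) // s + 1


@settings(derandomize=True, max_examples=30, deadline=None)
@given(seed=st.integers(0, 10_000), k=st.floats(0.0, 100.0))
def test_scale_equivariance_and_upper_bound(seed, k):
    rng = np.random.default_rng(seed)
    x = rng.normal(0, 5, (300, 2))
    rec = SignalRecord(x, FS)
    base = sliding_rms(rec, 50.0, 10.0)
    scaled = sliding_rms(SignalRecord(k * x, FS), 50.0, 10.0)
    assert np.allclose(scaled.values, k * base.values, rtol=1e-9, atol=1e-12)
    # every window RMS bounded by the window's max |sample|
    W, S = 50, 10
    for w in range(base.n_windows):
        assert np.all(base.values[w] <= np.abs(x[w * S : w * S + W]).max(axis=0) + 1e-12)


def test_window_labels_modal_with_earlier_class_tiebreak():
    labels = np.array(["rest"] * 100 + ["thumb"] * 100)
    rec = SignalRecord(np.ones((200, 1)), FS, labels=labels)
    feats = sliding_rms(rec, window_ms=200.0, step_ms=5.0)
    # single window covering exactly half rest / half thumb: tie → rest
    assert feats.n_windows == 1
    assert feats.labels[0] == "rest"


class TestStreaming:
    def test_matches_batch_on_random_input(self):
        rng = np.random.default_rng(1)
        x = rng.normal(0, 10, (1234, 3))
        batch = sliding_rms(SignalRecord(x, FS), 100.0, 7.0)
        stream = sliding_rms_streaming(
            np.array_split(x, 17), FS, 3, 100.0, 7.0
        )
        assert np.allclose(stream.values, batch.values, rtol=1e-9)
        assert np.allclose(stream.window_end_times, batch.window_end_times)

    def test_rows_emitted_as_samples_arrive(self):
        ext = StreamingRms(FS, 1, window_ms=100.0, step_ms=50.0)
        assert ext.push(np.zeros((99, 1))) == []
        rows = ext.push(np.ones((1, 1)))
        assert len(rows) == 1

    def test_short_stream_emits_nothing(self):
        ext = StreamingRms(FS, 2, window_ms=200.0)
        ext.push(np.ones((100, 2)))
        feats = ext.finalize()
        assert feats.n_windows == 0

    def test_concatenation_invariance(self):
        rng = np.random.default_rng(2)
        a, b = rng.normal(size=(400, 2)), rng.normal(size=(333, 2))
        one = sliding_rms_streaming([np.vstack([a, b])], FS, 2, 80.0, 15.0)
        two = sliding_rms_streaming([a, b], FS, 2, 80.0, 15.0)
        assert np.allclose(one.values, two.values, rtol=1e-12)


class TestMovingAverage:
    def _series(self, values):
        rec = SignalRecord(np.asarray(values, dtype=float)[:, None], FS)
        return sliding_rms(rec, 1.0, 1.0)

    def test_span_one_is_identity(self):
        feats = self._series(np.arange(10.0))
        out = moving_average(feats, 1)
        assert np.array_equal(out.values, feats.values)

    def test_constant_series_unchanged(self):
        feats = self._series(np.full(20, 4.0))
        assert np.allclose(moving_average(feats, 5).values, 4.0)

    def test_impulse_spreads_over_span(self):
        x = np.zeros(11)
        x[5] = 1.0
        out = moving_average(self._series(x), 5)
        expected = np.zeros(11)
        expected[3:8] = 0.2
        assert np.allclose(out.values[:, 0], expected)

    def test_output_length_preserved_at_edges(self):
        feats = self._series(np.arange(7.0))
        out = moving_average(feats, 5)
        assert out.n_windows == 7
        # leading edge uses a shrunken window: mean of first 3 values
        assert out.values[0, 0] == pytest.approx(np.mean([0, 1, 2]))

    def test_span_exceeding_length_rejected(self):
        with pytest.raises(ValueError, match="span"):
            moving_average(self._series(np.ones(4)), 9)


def test_total_activation():
    rec = SignalRecord(np.ones((300, 16)), FS)
    feats = sliding_rms(rec, 100.0, 10.0)
    assert np.all(total_activation(feats) == 16.0)
    # a single active channel dominates the sum
    x = np.zeros((300, 4))
    x[:, 2] = 5.0
    feats2 = sliding_rms(SignalRecord(x, FS), 100.0, 10.0)
    assert np.allclose(total_activation(feats2), feats2.values[:, 2])


def test_activation_sum_rises_during_flexion(flexion_features):
    total = total_activation(flexion_features)
    rest = total[flexion_features.labels == "rest"].mean()
    active = total[flexion_features.labels == "middle"].mean()
    assert active > rest


def test_errors_reported():
    rec = SignalRecord(np.ones((50, 1)), FS)
    with pytest.raises(ValueError, match="shorter than one window"):
        sliding_rms(rec, 200.0, 5.0)
    with pytest.raises(ValueError, match="whole number of samples"):
        sliding_rms(SignalRecord(np.ones((500, 1)), FS), 200.5, 5.0)
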