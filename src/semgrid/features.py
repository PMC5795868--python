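"""Sliding-window RMS feature extraction and moving-average smoothing.

The amplitude feature throughout is the windowed root-mean-square of
each channel: the record is divided into 200 ms windows advancing every
5 ms, and each window contributes one RMS value per channel. A centered
moving average is available for smoothing (display and, optionally,
pre-clustering).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .records import SignalRecord


@dataclass
class FeatureSeries:
    """Per-window, per-channel RMS amplitudes.

    ``values`` has shape ``(n_windows, n_channels)`` in μV;
    ``window_end_times`` marks the time of the last sample of each
    window (seconds). ``labels``, when present, holds one motion label
    per window (the modal sample label within the window).
    """

    values: np.ndarray
    window_ms: float
    step_ms: float
    window_end_times: np.ndarray
    channel_names: list[str]
    labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.window_end_times = np.asarray(self.window_end_times, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError(f"values must be 2-D, got shape {self.values.shape}")
        if np.any(self.values < 0):
            raise ValueError("RMS values must be non-negative")
        if len(self.window_end_times) != self.values.shape[0]:
            raise ValueError("window_end_times length mismatch")
        if self.labels is not None:
            self.labels = np.asarray(self.labels)
            if self.labels.shape[0] != self.values.shape[0]:
                raise ValueError("labels length mismatch")

    @property
    def n_windows(self) -> int:
        return self.values.shape[0]

    @property
    def n_channels(self) -> int:
        return self.values.shape[1]

    def class_order(self) -> list[str]:
        if self.labels is None:
            return []
        seen: dict[str, None] = {}
        for lab in self.labels:
            seen.setdefault(str(lab), None)
        return list(seen)


def _window_counts(n_samples: int, fs: float, window_ms: float, step_ms: float
                   ) -> tuple[int, int, int]:
    """Convert (window, step) to sample counts; validate integrality."""
    w_exact = window_ms * fs / 1000.0
    s_exact = step_ms * fs / 1000.0
    W, S = int(round(w_exact)), int(round(s_exact))
    if abs(w_exact - W) > 1e-9:
        raise ValueError(
            f"window of {window_ms} ms is not a whole number of samples at "
            f"{fs} Hz (remainder {w_exact - W:+.6g} samples)"
        )
    if abs(s_exact - S) > 1e-9:
        raise ValueError(
            f"step of {step_ms} ms is not a whole number of samples at "
            f"{fs} Hz (remainder {s_exact - S:+.6g} samples)"
        )
    if W < 1 or S < 1:
        raise ValueError(f"window ({W}) and step ({S}) must be >= 1 sample")
    if n_samples < W:
        raise ValueError(
            f"record of {n_samples} samples is shorter than one window ({W} samples)"
        )
    n_windows = (n_samples - W) // S + 1
    return W, S, n_windows


def window_labels(sample_labels: np.ndarray, W: int, S: int, n_windows: int
                  ) -> np.ndarray:
    """Modal sample label per window; ties go to the earliest-appearing class."""
    order: dict[str, int] = {}
    for lab in sample_labels:
        order.setdefault(str(lab), len(order))
    out = np.empty(n_windows, dtype=object)
    for w in range(n_windows):
        seg = sample_labels[w * S : w * S + W]
        uniq, counts = np.unique(seg.astype(str), return_counts=True)
        best = max(zip(uniq, counts), key=lambda uc: (uc[1], -order[uc[0]]))
        out[w] = best[0]
    return out.astype(str)


def sliding_rms(record: SignalRecord, window_ms: float = 200.0,
                step_ms: float = 5.0) -> FeatureSeries:
    """Windowed RMS of every channel: 200 ms windows every 5 ms by default.

    Windows are contiguous slices ``[w*S, w*S + W)``; a ragged final
    partial window is discarded, so
    ``n_windows = floor((n_samples - W) / S) + 1``.
    """
    W, S, n_windows = _window_counts(
        record.n_samples, record.sampling_rate, window_ms, step_ms
    )
    sq = record.samples**2
    csum = np.vstack([np.zeros((1, record.n_channels)), np.cumsum(sq, axis=0)])
    starts = np.arange(n_windows) * S
    means = (csum[starts + W] - csum[starts]) / W
    values = np.sqrt(np.maximum(means, 0.0))

    end_times = record.start_time + (starts + W) / record.sampling_rate
    labels = None
    if record.labels is not None:
        labels = window_labels(record.labels, W, S, n_windows)
    return FeatureSeries(values, window_ms, step_ms, end_times,
                         list(record.channel_names), labels)


class StreamingRms:
    """Incremental windowed-RMS extractor.

    Samples arrive in chunks via :meth:`push`; each window's RMS row is
    emitted as soon as its last sample has arrived. :meth:`finalize`
    returns a :class:`FeatureSeries` equal (to ~1e-9 relative) to the
    batch :func:`sliding_rms` of the concatenated input.
    """

    def __init__(self, sampling_rate: float, n_channels: int,
                 window_ms: float = 200.0, step_ms: float = 5.0,
                 channel_names: list[str] | None = None, start_time: float = 0.0):
        w_exact = window_ms * sampling_rate / 1000.0
        s_exact = step_ms * sampling_rate / 1000.0
        self.W, self.S = int(round(w_exact)), int(round(s_exact))
        if abs(w_exact - self.W) > 1e-9 or abs(s_exact - self.S) > 1e-9:
            raise ValueError("window/step must be whole numbers of samples")
        self.fs = sampling_rate
        self.n_channels = n_channels
        self.window_ms, self.step_ms = window_ms, step_ms
        self.channel_names = channel_names or [f"ch{i+1:02d}" for i in range(n_channels)]
        self.start_time = start_time
        self._buffer = np.zeros((0, n_channels))
        self._consumed = 0  # samples dropped from the front of the buffer
        self._rows: list[np.ndarray] = []
        self._end_times: list[float] = []

    def push(self, chunk: np.ndarray) -> list[np.ndarray]:
        """Feed a chunk of shape (n, n_channels); returns rows completed by it."""
        chunk = np.atleast_2d(np.asarray(chunk, dtype=np.float64))
        if chunk.shape[1] != self.n_channels:
            raise ValueError(
                f"chunk has {chunk.shape[1]} channels, expected {self.n_channels}"
            )
        self._buffer = np.vstack([self._buffer, chunk])
        new_rows: list[np.ndarray] = []
        while self._buffer.shape[0] >= self.W:
            window = self._buffer[: self.W]
            row = np.sqrt(np.mean(window**2, axis=0))
            end_sample = self._consumed + self.W
            self._end_times.append(self.start_time + end_sample / self.fs)
            new_rows.append(row)
            self._buffer = self._buffer[self.S :]
            self._consumed += self.S
        self._rows.extend(new_rows)
        return new_rows

    def finalize(self) -> FeatureSeries:
        values = (np.array(self._rows) if self._rows
                  else np.zeros((0, self.n_channels)))
        return FeatureSeries(values, self.window_ms, self.step_ms,
                             np.array(self._end_times), list(self.channel_names))


def sliding_rms_streaming(chunks, sampling_rate: float, n_channels: int,
                          window_ms: float = 200.0, step_ms: float = 5.0
                          ) -> FeatureSeries:
    """Run :class:`StreamingRms` over an iterable of sample chunks."""
    extractor = StreamingRms(sampling_rate, n_channels, window_ms, step_ms)
    for chunk in chunks:
        extractor.push(chunk)
    return extractor.finalize()


def moving_average(features: FeatureSeries, span_windows: int = 41) -> FeatureSeries:
    """Centered per-channel moving average with shrunken edge windows.

    Output length equals input length; at the edges the average runs
    over the available part of the span only.
    """
    if span_windows < 1:
        raise ValueError(f"span must be >= 1, got {span_windows}")
    n = features.n_windows
    if span_windows > n:
        raise ValueError(f"span {span_windows} exceeds series length {n}")
    if span_windows == 1:
        smoothed = features.values.copy()
    else:
        half_lo = span_windows // 2
        half_hi = span_windows - 1 - half_lo
        csum = np.vstack([np.zeros((1, features.n_channels)),
                          np.cumsum(features.values, axis=0)])
        idx = np.arange(n)
        lo = np.maximum(idx - half_lo, 0)
        hi = np.minimum(idx + half_hi, n - 1) + 1
        smoothed = (csum[hi] - csum[lo]) / (hi - lo)[:, None]
    return FeatureSeries(smoothed, features.window_ms, features.step_ms,
                         features.window_end_times.copy(),
                         list(features.channel_names),
                         None if features.labels is None else features.labels.copy())


def total_activation(features: FeatureSeries) -> np.ndarray:
    """Per-window sum of RMS amplitudes across all channels."""
    return features.values.sum(axis=1)
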