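"""Core in-memory containers for multichannel surface-EMG recordings.

All amplitudes inside the package are in microvolts (μV); unit conversions
happen only at the I/O boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class SignalRecord:
    """A multichannel, uniformly sampled sEMG time series.

    Parameters
    ----------
    samples
        Array of shape ``(n_samples, n_channels)`` in μV.
    sampling_rate
        Sampling frequency in Hz.
    channel_names
        One label per channel (``ch01`` ... by convention).
    labels
        Optional per-sample motion labels (array of strings, length
        ``n_samples``).
    start_time
        Time of the first sample in seconds.
    """

    samples: np.ndarray
    sampling_rate: float
    channel_names: list[str] = field(default_factory=list)
    labels: np.ndarray | None = None
    start_time: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 2:
            raise ValueError(
                f"samples must be 2-D (n_samples, n_channels), got shape {self.samples.shape}"
            )
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples contain non-finite values")
        if self.sampling_rate <= 0:
            raise ValueError(f"sampling_rate must be positive, got {self.sampling_rate}")
        if not self.channel_names:
            self.channel_names = [f"ch{i + 1:02d}" for i in range(self.samples.shape[1])]
        if len(self.channel_names) != self.samples.shape[1]:
            raise ValueError(
                f"{len(self.channel_names)} channel names for {self.samples.shape[1]} channels"
            )
        if self.labels is not None:
            self.labels = np.asarray(self.labels)
            if self.labels.shape[0] != self.samples.shape[0]:
                raise ValueError(
                    f"labels length {self.labels.shape[0]} != n_samples {self.samples.shape[0]}"
                )

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def n_channels(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        """Record duration in seconds."""
        return self.n_samples / self.sampling_rate

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds, starting at ``start_time``."""
        return self.start_time + np.arange(self.n_samples) / self.sampling_rate

    def class_order(self) -> list[str]:
        """Distinct labels in order of first appearance (empty if unlabeled)."""
        if self.labels is None:
            return []
        seen: dict[str, None] = {}
        for lab in self.labels:
            seen.setdefault(str(lab), None)
        return list(seen)

    def copy_with(self, samples: np.ndarray) -> "SignalRecord":
        """Return a record with the same metadata but new sample values."""
        return SignalRecord(
            samples=np.asarray(samples, dtype=np.float64),
            sampling_rate=self.sampling_rate,
            channel_names=list(self.channel_names),
            labels=None if self.labels is None else self.labels.copy(),
            start_time=self.start_time,
        )
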