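"""Signal conditioning: bandpass and power-line notch filtering.

The acquisition chain band-limits each bipolar channel to 5–450 Hz and
removes mains interference with a notch. Filters are designed digitally
(order-4 Butterworth bandpass; second-order IIR notch) and applied per
channel, either forward-backward (zero-phase, the offline default) or
causally (matching a real-time deployment); the two modes are not
identical and the causal mode flags a warm-up region.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .records import SignalRecord


@dataclass
class FilterSpec:
    """Parametric description of a bandpass or notch filter.

    For ``kind="bandpass"``: ``low_hz``/``high_hz`` corner frequencies
    and Butterworth ``order``. For ``kind="notch"``: ``center_hz`` and
    ``quality_factor`` (center / −3 dB bandwidth). ``zero_phase``
    selects forward-backward application.
    """

    kind: str
    low_hz: float | None = None
    high_hz: float | None = None
    center_hz: float | None = None
    quality_factor: float = 30.0
    order: int = 4
    zero_phase: bool = True

    def validate(self, sampling_rate: float) -> None:
        nyq = sampling_rate / 2
        if self.kind == "bandpass":
            if self.low_hz is None or self.high_hz is None:
                raise ValueError("bandpass spec requires low_hz and high_hz")
            if not (0 < self.low_hz < self.high_hz):
                raise ValueError(
                    f"bandpass corners must satisfy 0 < low < high, got "
                    f"({self.low_hz}, {self.high_hz})"
                )
            if self.high_hz >= nyq:
                raise ValueError(
                    f"bandpass high corner {self.high_hz} Hz >= Nyquist {nyq} Hz"
                )
            if self.order < 1:
                raise ValueError(f"order must be >= 1, got {self.order}")
        elif self.kind == "notch":
            if self.center_hz is None:
                raise ValueError("notch spec requires center_hz")
            if not (0 < self.center_hz < nyq):
                raise ValueError(
                    f"notch center {self.center_hz} Hz outside (0, Nyquist={nyq}) Hz"
                )
            if self.quality_factor <= 0:
                raise ValueError(f"quality_factor must be positive, got {self.quality_factor}")
        else:
            raise ValueError(f"unknown filter kind {self.kind!r}")


def bandpass_spec(low_hz: float = 5.0, high_hz: float = 450.0, order: int = 4,
                  zero_phase: bool = True) -> FilterSpec:
    """Default acquisition bandpass: 5–450 Hz, order-4 Butterworth."""
    return FilterSpec("bandpass", low_hz=low_hz, high_hz=high_hz, order=order,
                      zero_phase=zero_phase)


def notch_spec(center_hz: float = 60.0, quality_factor: float = 30.0,
               zero_phase: bool = True) -> FilterSpec:
    """Default power-line notch (60 Hz mains; use 50 Hz where applicable)."""
    return FilterSpec("notch", center_hz=center_hz, quality_factor=quality_factor,
                      zero_phase=zero_phase)


def _design_ba(spec: FilterSpec, fs: float) -> tuple[np.ndarray, np.ndarray]:
    if spec.kind == "bandpass":
        b, a = sps.butter(spec.order, [spec.low_hz, spec.high_hz], btype="bandpass", fs=fs)
    else:
        b, a = sps.iirnotch(spec.center_hz, spec.quality_factor, fs=fs)
    return b, a


def warmup_samples(spec: FilterSpec) -> int:
    """Length of the causal-mode transient region flagged to callers."""
    return max(spec.order * 3, 100)


def _apply(record: SignalRecord, spec: FilterSpec) -> SignalRecord:
    spec.validate(record.sampling_rate)
    b, a = _design_ba(spec, record.sampling_rate)
    if spec.zero_phase:
        padlen = 3 * (max(len(b), len(a)) - 1)
        if record.n_samples <= padlen:
            raise ValueError(
                f"record of {record.n_samples} samples is shorter than the "
                f"filter warm-up length ({padlen + 1} samples)"
            )
        out = sps.filtfilt(b, a, record.samples, axis=0)
    else:
        if record.n_samples <= warmup_samples(spec):
            raise ValueError(
                f"record of {record.n_samples} samples is shorter than the "
                f"causal warm-up length ({warmup_samples(spec)} samples)"
            )
        out = sps.lfilter(b, a, record.samples, axis=0)
    return record.copy_with(out)


def bandpass(record: SignalRecord, spec: FilterSpec | None = None) -> SignalRecord:
    """Bandpass-filter every channel independently (default 5–450 Hz)."""
    spec = spec or bandpass_spec()
    if spec.kind != "bandpass":
        raise ValueError(f"bandpass() requires a bandpass spec, got {spec.kind!r}")
    return _apply(record, spec)


def notch(record: SignalRecord, spec: FilterSpec | None = None) -> SignalRecord:
    """Notch-filter every channel independently (default 60 Hz, Q=30)."""
    spec = spec or notch_spec()
    if spec.kind != "notch":
        raise ValueError(f"notch() requires a notch spec, got {spec.kind!r}")
    return _apply(record, spec)


def frequency_response(spec: FilterSpec, sampling_rate: float,
                       freqs) -> np.ndarray:
    """Gain of the designed filter, in dB, at each requested frequency.

    In zero-phase mode the effective magnitude response is squared
    (the filter runs forward and backward), so gains in dB double.
    """
    freqs = np.atleast_1d(np.asarray(freqs, dtype=float))
    nyq = sampling_rate / 2
    if np.any(freqs <= 0) or np.any(freqs >= nyq):
        raise ValueError(f"frequencies must lie in (0, Nyquist={nyq}) Hz")
    spec.validate(sampling_rate)
    b, a = _design_ba(spec, sampling_rate)
    _, h = sps.freqz(b, a, worN=freqs, fs=sampling_rate)
    gain_db = 20 * np.log10(np.maximum(np.abs(h), 1e-300))
    if spec.zero_phase:
        gain_db = 2 * gain_db
    return gain_db
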