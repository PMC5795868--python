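"""Synthetic high-density sEMG session generator.

Generates labeled 16-channel (or arbitrary) grid recordings with
motion-dependent spatial amplitude structure, so that the whole
feature/pattern/classification chain is testable without hardware.

Signal model, per channel ``c`` while motion ``m`` is active::

    x_c(t) = a_{c,m} * e_c(t) + n_c(t)

where ``n_c`` is white Gaussian noise with standard deviation
``noise_floor`` (amplifier/electrode noise), and ``e_c`` is unit-RMS
band-limited Gaussian noise confined to ``emg_band`` — an interference
EMG surrogate whose second-order statistics (amplitude and spectrum)
match what the downstream RMS features consume. Amplitudes ramp
linearly over ``onset_ramp`` seconds at motion transitions. Channels
are independent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from scipy import signal as sps

import numpy as np

from .layout import ElectrodeLayout
from .records import SignalRecord


@dataclass
class SimulationConfig:
    """Full description of one synthetic recording session.

    ``activation_map[motion]`` holds one target RMS amplitude (μV) per
    channel: the RMS of the EMG-like component while that motion is
    held. The noise floor adds in quadrature, so the measured RMS of a
    steady segment converges to ``sqrt(a**2 + noise_floor**2)``.
    """

    layout: ElectrodeLayout
    classes: list[str]
    activation_map: dict[str, np.ndarray]
    schedule: list[tuple[str, float]]
    sampling_rate: float = 1000.0
    noise_floor: float = 3.0
    emg_band: tuple[float, float] = (20.0, 450.0)
    onset_ramp: float = 0.1
    seed: int = 0

    @property
    def n_channels(self) -> int:
        return self.layout.n_channels

    def validate(self) -> None:
        if self.sampling_rate <= 0:
            raise ValueError(f"sampling_rate must be positive, got {self.sampling_rate}")
        if self.noise_floor <= 0:
            raise ValueError(f"noise_floor must be positive, got {self.noise_floor}")
        low, high = self.emg_band
        if not (0 < low < high < self.sampling_rate / 2):
            raise ValueError(
                f"emg_band {self.emg_band} must satisfy 0 < low < high < Nyquist "
                f"({self.sampling_rate / 2} Hz)"
            )
        if not self.schedule:
            raise ValueError("schedule is empty")
        if self.onset_ramp < 0:
            raise ValueError(f"onset_ramp must be >= 0, got {self.onset_ramp}")
        for motion, dur in self.schedule:
            if motion not in self.classes:
                raise ValueError(f"scheduled motion {motion!r} not in classes {self.classes}")
            if dur <= 0:
                raise ValueError(f"schedule duration for {motion!r} must be positive, got {dur}")
        for cls in self.classes:
            if cls not in self.activation_map:
                raise ValueError(f"class {cls!r} missing from activation_map")
            amps = np.asarray(self.activation_map[cls], dtype=float)
            if amps.shape != (self.n_channels,):
                raise ValueError(
                    f"activation_map[{cls!r}] has shape {amps.shape}, "
                    f"expected ({self.n_channels},)"
                )
            if np.any(amps < 0):
                raise ValueError(f"activation_map[{cls!r}] has negative amplitudes")


def _bandlimited_unit_noise(
    rng: np.random.Generator, n: int, fs: float, band: tuple[float, float]
) -> np.ndarray:
    """White Gaussian noise band-limited to `band`, renormalized to unit RMS.

    Forward-backward 4th-order Butterworth keeps the component zero-phase;
    the realized RMS over the full draw is renormalized to exactly 1 so
    that amplitude calibration downstream is exact in expectation.
    """
    sos = sps.butter(4, band, btype="bandpass", fs=fs, output="sos")
    white = rng.standard_normal(n)
    shaped = sps.sosfiltfilt(sos, white)
    rms = np.sqrt(np.mean(shaped**2))
    return shaped / rms


def _amplitude_envelope(config: SimulationConfig, channel: int, n_total: int) -> np.ndarray:
    """Per-sample target amplitude for one channel, with linear onset ramps."""
    fs = config.sampling_rate
    env = np.empty(n_total)
    ramp_n = int(round(config.onset_ramp * fs))
    pos = 0
    prev_amp = 0.0
    for motion, dur in config.schedule:
        seg_n = int(round(dur * fs))
        seg_n = min(seg_n, n_total - pos)
        amp = float(np.asarray(config.activation_map[motion], dtype=float)[channel])
        env[pos : pos + seg_n] = amp
        if ramp_n > 0 and amp != prev_amp:
            k = min(ramp_n, seg_n)
            env[pos : pos + k] = np.linspace(prev_amp, amp, k + 1)[1:]
        prev_amp = amp
        pos += seg_n
    return env


def generate_session(config: SimulationConfig) -> SignalRecord:
    """Render a full labeled session according to `config`.

    Identical config (including seed) gives bit-identical output.
    """
    config.validate()
    fs = config.sampling_rate
    seg_samples = [int(round(dur * fs)) for _, dur in config.schedule]
    n_total = int(sum(seg_samples))

    rng = np.random.default_rng(config.seed)
    n_ch = config.n_channels
    samples = np.empty((n_total, n_ch))
    for c in range(n_ch):
        emg = _bandlimited_unit_noise(rng, n_total, fs, config.emg_band)
        noise = rng.standard_normal(n_total) * config.noise_floor
        samples[:, c] = _amplitude_envelope(config, c, n_total) * emg + noise

    labels = np.empty(n_total, dtype=object)
    pos = 0
    for (motion, _), seg_n in zip(config.schedule, seg_samples):
        labels[pos : pos + seg_n] = motion
        pos += seg_n

    return SignalRecord(
        samples=samples,
        sampling_rate=fs,
        channel_names=config.layout.channel_names,
        labels=labels.astype(str),
    )


# Default finger-flexion study: 16 bipolar channels on a 4x4 grid over the
# forearm flexor group, five single-finger flexions plus rest. Channels 1,
# 4 and 8 (1-based) are active in every flexion (muscles shared across
# fingers); channel 5 is active only for the middle finger; each other
# finger also gets one selective channel, and the remaining channels carry
# distinct moderate amplitudes so all five flexions are mutually separable.
FLEXION_CLASSES = ["rest", "thumb", "index", "middle", "ring", "little"]

_COMMON_CHANNELS = {0: 45.0, 3: 40.0, 7: 50.0}  # 0-based: channels 1, 4, 8
_SELECTIVE_CHANNELS = {  # one dedicated channel per finger; middle -> channel 5
    "thumb": 9,
    "index": 11,
    "middle": 4,
    "ring": 13,
    "little": 15,
}
_SELECTIVE_AMP = 55.0


def default_finger_flexion_config(
    seed: int = 0,
    noise_floor: float = 3.0,
    separation_scale: float = 1.0,
    cycles: int = 4,
    segment_s: float = 2.0,
) -> SimulationConfig:
    """Canonical synthetic single-finger-flexion session.

    ``separation_scale`` multiplies every activation amplitude; 1.0 is
    the strongly separated default, values toward 0 push the classes
    into the noise floor. The schedule interleaves rest with each
    flexion, repeated ``cycles`` times, so block-wise train/test splits
    contain every class on both sides.
    """
    layout = ElectrodeLayout.grid(4, 4, inter_electrode_distance_mm=10.0)
    n_ch = 16
    amap: dict[str, np.ndarray] = {"rest": np.zeros(n_ch)}
    for i, motion in enumerate(m for m in FLEXION_CLASSES if m != "rest"):
        amps = np.zeros(n_ch)
        for ch, a in _COMMON_CHANNELS.items():
            amps[ch] = a
        amps[_SELECTIVE_CHANNELS[motion]] = _SELECTIVE_AMP
        # graded background on the remaining channels, distinct per finger
        for j, ch in enumerate(c for c in range(n_ch)
                               if c not in _COMMON_CHANNELS
                               and c not in _SELECTIVE_CHANNELS.values()):
            amps[ch] = 6.0 + 4.0 * ((i + j) % 5)
        amap[motion] = amps * separation_scale

    schedule: list[tuple[str, float]] = []
    for _ in range(cycles):
        schedule.append(("rest", segment_s))
        for motion in FLEXION_CLASSES[1:]:
            schedule.append((motion, segment_s))

    return SimulationConfig(
        layout=layout,
        classes=list(FLEXION_CLASSES),
        activation_map=amap,
        schedule=schedule,
        sampling_rate=1000.0,
        noise_floor=noise_floor,
        emg_band=(20.0, 450.0),
        onset_ramp=0.1,
        seed=seed,
    )


# -- config (de)serialization -------------------------------------------


def config_to_dict(config: SimulationConfig) -> dict:
    return {
        "sampling_rate": config.sampling_rate,
        "noise_floor": config.noise_floor,
        "emg_band": list(config.emg_band),
        "onset_ramp": config.onset_ramp,
        "seed": config.seed,
        "classes": list(config.classes),
        "layout": config.layout.to_dict(),
        "activation_map": {
            m: [float(a) for a in amps] for m, amps in config.activation_map.items()
        },
        "schedule": [[m, float(d)] for m, d in config.schedule],
    }


def config_from_dict(d: dict) -> SimulationConfig:
    return SimulationConfig(
        layout=ElectrodeLayout.from_dict(d["layout"]),
        classes=[str(c) for c in d["classes"]],
        activation_map={
            str(m): np.asarray(a, dtype=float) for m, a in d["activation_map"].items()
        },
        schedule=[(str(m), float(dur)) for m, dur in d["schedule"]],
        sampling_rate=float(d.get("sampling_rate", 1000.0)),
        noise_floor=float(d.get("noise_floor", 3.0)),
        emg_band=tuple(d.get("emg_band", (20.0, 450.0))),
        onset_ramp=float(d.get("onset_ramp", 0.1)),
        seed=int(d.get("seed", 0)),
    )
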