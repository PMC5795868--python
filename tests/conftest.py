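import numpy as np
import pytest

from semgrid import (
    ElectrodeLayout,
    SimulationConfig,
    bandpass,
    default_finger_flexion_config,
    generate_session,
    notch,
    sliding_rms,
)


@pytest.fixture(scope="session")
def flexion_config():
    """Small finger-flexion session config shared by read-only tests."""
    return default_finger_flexion_config(seed=7, cycles=2, segment_s=1.0)


@pytest.fixture(scope="session")
def flexion_session(flexion_config):
    return generate_session(flexion_config)


@pytest.fixture(scope="session")
def flexion_features(flexion_session):
    """Filtered + windowed-RMS features for the shared flexion session."""
    return sliding_rms(notch(bandpass(flexion_session)))


def make_two_motion_config(seed: int = 0, segment_s: float = 1.0,
                           cycles: int = 3) -> SimulationConfig:
    """Two strongly separated motions (hand-close-like vs two-finger-like)
    on a 2x2 grid, alternating in the schedule."""
    layout = ElectrodeLayout.grid(2, 2)
    amap = {
        "hand_close": np.array([60.0, 10.0, 45.0, 5.0]),
        "two_finger": np.array([10.0, 60.0, 5.0, 45.0]),
    }
    schedule = [(m, segment_s) for _ in range(cycles)
                for m in ("hand_close", "two_finger")]
    return SimulationConfig(
        layout=layout, classes=["hand_close", "two_finger"],
        activation_map=amap, schedule=schedule, noise_floor=3.0, seed=seed,
    )


def sine_record(freq_hz: float, amplitude_uv: float, fs: float = 1000.0,
                duration_s: float = 2.0, n_channels: int = 1):
    """Single-tone test record (the bench verification signal is a
    100 Hz, 1 mV sine)."""
    from semgrid import SignalRecord

    t = np.arange(int(round(duration_s * fs))) / fs
    x = amplitude_uv * np.sin(2 * np.pi * freq_hz * t)
    return SignalRecord(np.tile(x[:, None], (1, n_channels)), fs)
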