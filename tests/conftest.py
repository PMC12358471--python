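import numpy as np
import pytest

from preictal import Recording, SynthConfig, generate_labeled_segments


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_config():
    """Cheap 2-channel generator config for unit tests."""
    return SynthConfig(n_channels=2, seed=42)


@pytest.fixture(scope="session")
def separated_segments():
    """Strongly class-separated single-channel segments, shared across tests."""
    config = SynthConfig(n_channels=1, seed=3, class_separation=3.0)
    return generate_labeled_segments(config, 60)


@pytest.fixture
def toy_recording():
    """Deterministic 2-channel 60-s ramp recording at 256 Hz."""
    fs = 256
    n = fs * 60
    t = np.arange(n) / fs
    samples = np.stack([np.sin(2 * np.pi * 10 * t), np.cos(2 * np.pi * 6 * t)]) * 3e-5
    return Recording(
        samples=samples,
        sampling_rate=fs,
        channel_names=["C3", "C4"],
        subject_id="chb00",
        session_id="chb00_01",
    )
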