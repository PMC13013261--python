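import numpy as np
import pytest

from cerauto.signals import BeatSeries, UniformSignal
from cerauto.synth import SynthConfig, generate_recording


def make_beats(values, spacing_s=0.8, t0=0.0):
    values = np.asarray(values, dtype=float)
    return BeatSeries(t0 + spacing_s * np.arange(values.size), values)


@pytest.fixture(scope="session")
def clean_recording():
    """Noise-free 300-s recording at 75 bpm with its ground truth."""
    cfg = SynthConfig(duration_s=300.0, hr_bpm=75.0, resp_bpm=6.0, seed=7, noise_sd={})
    return generate_recording(cfg)


@pytest.fixture(scope="session")
def noisy_recording():
    """Default-noise 300-s paced-6 recording with its ground truth."""
    cfg = SynthConfig(duration_s=300.0, resp_bpm=6.0, seed=11)
    return generate_recording(cfg)


@pytest.fixture
def white_signal():
    rng = np.random.default_rng(123)
    return UniformSignal(rng.standard_normal(2460), fs=4.0)  # 615 s at 4 Hz
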