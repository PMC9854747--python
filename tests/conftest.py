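import numpy as np
import pytest

from fecgsqa.preprocess import Recording, Segment
from fecgsqa.synthetic_fecg import SynthesisConfig, generate_recording


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20230104)


@pytest.fixture(scope="session")
def clean_recording():
    """15 s noise-free synthetic recording at 140 bpm."""
    cfg = SynthesisConfig(duration=15.0, noise_amplitude_ratio=0.0,
                          fetal_rate=140.0, baseline_wander_amplitude=0.0,
                          seed=11)
    return generate_recording(cfg)


@pytest.fixture
def sine_recording():
    fs = 1000.0
    t = np.arange(int(10 * fs)) / fs
    return Recording(np.sin(2 * np.pi * 10.0 * t), fs)


def make_segment(samples, fs=1000.0, segment_id="seg"):
    return Segment(samples=np.asarray(samples, dtype=float),
                   sampling_frequency=fs, segment_id=segment_id)


@pytest.fixture
def noise_segment(rng):
    return make_segment(rng.standard_normal(3000))
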