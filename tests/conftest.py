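import numpy as np
import pytest

from neowave import SynthConfig, generate_recording
from neowave.synth import RaterNoise


@pytest.fixture(scope="session")
def fs() -> float:
    return 256.0


@pytest.fixture(scope="session")
def small_cfg() -> SynthConfig:
    """One 30-s seizure in a 60-s two-channel recording, noiseless raters."""
    return SynthConfig(n_channels=2, duration=60.0,
                       seizure_intervals=((20.0, 50.0),),
                       rater_noise=RaterNoise(jitter_s=0.0, miss_prob=0.0),
                       seed=11)


@pytest.fixture(scope="session")
def small_recording(small_cfg):
    return generate_recording(small_cfg)


def sine(freq: float, fs: float, duration: float, amplitude: float = 1.0,
         phase: float = 0.0) -> np.ndarray:
    t = np.arange(int(round(duration * fs))) / fs
    return amplitude * np.cos(2 * np.pi * freq * t + phase)
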