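import numpy as np
import pytest

from cabinpulse.simulate import RadarConfig, SceneConfig, simulate_recording


@pytest.fixture(scope="session")
def radar():
    """Default radar timing: 58-63.5 GHz, 3 MHz, 128 samples, 50 ms frames."""
    return RadarConfig()


@pytest.fixture(scope="session")
def clean_recording():
    """90 s drive at constant 72 bpm with respiration but no vibration."""
    scene = SceneConfig(hr=72.0, vib_rms=0.0, noise_snr=35.0, seed=7)
    cube, truth = simulate_recording(RadarConfig(), scene)
    return cube, truth, scene


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
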