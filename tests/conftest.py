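import numpy as np
import pytest

from fetanc.simulate import SimConfig, simulate_recording


@pytest.fixture(scope="session")
def small_sim():
    """A short 3-channel recording for fast structural tests."""
    cfg = SimConfig(fs=250.0, duration=12.0, n_abdominal_channels=3, seed=11)
    return simulate_recording(cfg)


@pytest.fixture(scope="session")
def clean_sim():
    """Nearly noise-free recording (40 dB): fetal component dominates residual."""
    cfg = SimConfig(fs=250.0, duration=12.0, n_abdominal_channels=3,
                    noise_level_db=40.0, seed=13)
    return simulate_recording(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
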