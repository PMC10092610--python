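import numpy as np
import pytest
from hypothesis import settings as hypothesis_settings

from ctcgamma import synth

hypothesis_settings.register_profile("deterministic", derandomize=True)
hypothesis_settings.load_profile("deterministic")

FS = 1000.0  # analyses reach 80 Hz, so 1 kHz is lossless and fast


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def fast_config():
    """A small, quick session: 10 trials at 1 kHz."""
    return synth.SessionConfig(
        sampling_rate=FS, n_trials_per_rat=5, n_rats=2, seed=7,
    )


def quiet_config(**overrides):
    """Config with every signal component off unless explicitly enabled."""
    base = dict(
        sampling_rate=FS,
        n_trials_per_rat=5,
        n_rats=2,
        background_gains={"delta": 0.0, "theta": 0.0, "sigma": 0.0,
                          "beta": 0.0, "gamma": 0.0},
        evoked_amplitude=0.0,
        induced_gain_beta=0.0,
        induced_gain_gamma=0.0,
        broadband_noise_gain=0.0,
        pink_gain=0.0,
        seed=3,
    )
    base.update(overrides)
    return synth.SessionConfig(**base)
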