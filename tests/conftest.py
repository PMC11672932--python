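import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("repeatable", derandomize=True, deadline=None)
settings.load_profile("repeatable")

from eegbeats.core import AnxietyLevel
from eegbeats.denoise import CAEConfig, train_cae
from eegbeats.harmonics import train_harmonic_scorer
from eegbeats.synthetic import simulate_recording

FS = 256.0


@pytest.fixture(scope="session")
def clean_recordings():
    """Twelve clean recordings covering all four classes."""
    return [
        simulate_recording(AnxietyLevel(i % 4), duration_s=6.0, fs=FS, n_channels=2, seed=i)
        for i in range(12)
    ]


@pytest.fixture(scope="session")
def cae_model(clean_recordings):
    """One production-strength autoencoder, shared across the session."""
    return train_cae(clean_recordings, CAEConfig(), seed=1)


@pytest.fixture(scope="session")
def harmonic_scorer():
    return train_harmonic_scorer(n_samples=500, fs=FS, seed=0)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
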