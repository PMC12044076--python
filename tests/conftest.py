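import numpy as np
import pytest

from sleepcrit import synthetic_data as sd


@pytest.fixture(scope="session")
def tiny_config() -> sd.SyntheticStudyConfig:
    """Small paired study: 4 subjects, 3 channels, 64 Hz, 6+2 epochs."""
    return sd.SyntheticStudyConfig(
        n_subjects=4, n_young=2, n_middle=2,
        channel_names=("Fz", "Cz", "Pz"), fs=64.0,
        n_nrem=6, n_rem=2, seed=42,
    )


@pytest.fixture(scope="session")
def tiny_study(tiny_config):
    return sd.generate_study(tiny_config)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
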