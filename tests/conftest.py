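import numpy as np
import pytest
from hypothesis import settings

import protoseg as ps

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_config() -> ps.SynthConfig:
    """Desk-scale generator conditions: standardization makes every case
    21 x 3 x 256 x 256 regardless of the raw grid."""
    return ps.SynthConfig(n_slices=60, grid=(96, 96))


@pytest.fixture(scope="session")
def case(small_config):
    return ps.generate_case(small_config, seed=42)


@pytest.fixture(scope="session")
def stack(case) -> ps.SliceStack:
    vol, lab = case
    return ps.preprocess_case(vol, lab)


@pytest.fixture(scope="session")
def tiny_dataset(small_config) -> list:
    """Six preprocessed cases, enough for episode sampling and k-fold splits."""
    out = []
    for i in range(6):
        vol, lab = ps.generate_case(small_config, seed=100 + i)
        out.append(ps.preprocess_case(vol, lab))
    return out


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(0)
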