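import numpy as np
import pytest

from multifission.synthetic_data import SyntheticConfig
from multifission.titration_model import ModelParams


@pytest.fixture
def default_params() -> ModelParams:
    return ModelParams()


@pytest.fixture
def small_synth_config() -> SyntheticConfig:
    """A fast config: few cells, noise on, all five division stages."""
    return SyntheticConfig(seed=11, n_cells=100, intensity_noise_cv=0.1)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
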