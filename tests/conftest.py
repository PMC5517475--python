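import numpy as np
import pytest

from ailum.config import AcquisitionConfig, NoiseModel


@pytest.fixture
def cfg() -> AcquisitionConfig:
    """Default two-photon configuration (alpha=2, B=12, S_sat=250, S0=125)."""
    return AcquisitionConfig()


@pytest.fixture
def noiseless() -> NoiseModel:
    return NoiseModel()


@pytest.fixture
def shot() -> NoiseModel:
    return NoiseModel(shot_noise=True)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
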