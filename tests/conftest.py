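import numpy as np
import pytest

from procode.core_model import NeuronParams
from procode.plasticity import PlasticityParams


@pytest.fixture(scope="session")
def neuron() -> NeuronParams:
    return NeuronParams()


@pytest.fixture(scope="session")
def plasticity() -> PlasticityParams:
    return PlasticityParams()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
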