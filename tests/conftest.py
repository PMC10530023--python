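import numpy as np
import pytest

from phagevolve import ModelParams, PopulationState


@pytest.fixture
def params():
    return ModelParams.paper_defaults()


@pytest.fixture
def s4_state():
    """Default 3-transfer starting condition: S0 = K/100, V0 = 1e4."""
    return PopulationState(t=0.0, S=1e6, V=1e4)


@pytest.fixture
def rng():
    return np.random.default_rng(20230731)
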