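import numpy as np
import pytest

from loopsurv import ModelParameters


@pytest.fixture
def default_params() -> ModelParameters:
    """Standard constants, lethalities unset."""
    return ModelParameters()


@pytest.fixture
def a549_params() -> ModelParameters:
    """Lung-adenocarcinoma-like lethality parameters from the reference panel."""
    return ModelParameters(k_idsb=4.83e-3, k_cdsb=0.169)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
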