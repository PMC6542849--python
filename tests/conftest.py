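import numpy as np
import pytest

from ionsizing.electrolyte import ElectrolyteCondition
from ionsizing.pore import PoreModel


@pytest.fixture
def nacl_250mM() -> ElectrolyteCondition:
    return ElectrolyteCondition.from_salt("NaCl", 0.25)


@pytest.fixture
def charged_pore() -> PoreModel:
    return PoreModel(d_minor=0.5, d_major=0.5, theta=10.0, t_mem=10.0, rho_s=-0.19)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
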