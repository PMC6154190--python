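import numpy as np
import pytest

from oxflow.chromophores import ChromophoreLibrary
from oxflow.forward_models import TissueModel


@pytest.fixture(scope="session")
def lib() -> ChromophoreLibrary:
    return ChromophoreLibrary.default()


@pytest.fixture(scope="session")
def truth_tissue() -> TissueModel:
    # canonical simulation truth: StO2 = 40/53 = 75.5%
    return TissueModel(WF=0.8, Hb_b=13.0, HbO2_b=40.0, A=0.8, alpha=2.6)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
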