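import numpy as np
import pytest

from famrare import DiseaseModel, VariantPanel


@pytest.fixture
def rng():
    return np.random.default_rng(20140101)


@pytest.fixture
def baseline_panel():
    """Ten rare variants at MAF 0.5%."""
    return VariantPanel(maf=np.full(10, 0.005))


@pytest.fixture
def baseline_model():
    """Background risk 1%, four causal variants with OR 2."""
    beta = np.zeros(10)
    beta[:4] = np.log(2.0)
    return DiseaseModel(c=0.01, beta=beta)


@pytest.fixture
def common_panel():
    """A small common-variant panel where transmissions are plentiful."""
    return VariantPanel(maf=np.array([0.05, 0.10, 0.20]))


@pytest.fixture
def common_model():
    return DiseaseModel(c=0.05, beta=np.array([np.log(3.0), 0.0, 0.0]))
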