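import numpy as np
import pytest

from tcrint.synthetic import ToyComplexSpec, make_toy_complex


@pytest.fixture(scope="session")
def toy():
    """Default miniature five-chain complex with planted ground truth."""
    return make_toy_complex(ToyComplexSpec())


@pytest.fixture(scope="session")
def toy_complex(toy):
    return toy[0]


@pytest.fixture(scope="session")
def toy_truth(toy):
    return toy[1]


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
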