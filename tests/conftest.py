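import numpy as np
import pytest

from megalpha.layout import build_adjacency, make_layout


@pytest.fixture(scope="session")
def layout102():
    return make_layout(102)


@pytest.fixture(scope="session")
def adjacency102(layout102):
    return build_adjacency(layout102)


@pytest.fixture(scope="session")
def layout20():
    return make_layout(20)


@pytest.fixture(scope="session")
def adjacency20(layout20):
    return build_adjacency(layout20)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
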