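import numpy as np
import pytest

from bristlephylo import mk, synthdata, treeio


@pytest.fixture
def cherry():
    return treeio.parse_tree("(A:1,B:1);")


@pytest.fixture
def three_tip():
    return treeio.parse_tree("((A:1,B:1):1,C:2);")


@pytest.fixture
def four_tip():
    return treeio.parse_tree("((A:1,B:1):2,(C:2,D:2):1);")


@pytest.fixture
def er_q():
    return mk.QMatrix.from_params("ER", 2, [0.5])


@pytest.fixture
def yule50():
    return synthdata.simulate_tree(50, seed=1234)
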