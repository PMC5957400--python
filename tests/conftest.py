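import numpy as np
import pytest

import geneshop as gs
from geneshop.likelihood import jc, poisson


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def yule12():
    return gs.simulate_yule(12, 1.0, seed=7)


@pytest.fixture
def small_tree():
    return gs.parse_newick("((A:1,B:1):1,C:2);")


@pytest.fixture(params=["nt", "aa"], ids=["jc", "poisson"])
def model(request):
    return jc() if request.param == "nt" else poisson()
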