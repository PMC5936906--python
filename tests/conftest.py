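import numpy as np
import pytest

from fslb import GammaRates, PhyloTree, lg_model, poisson_model


@pytest.fixture(scope="session")
def lg():
    return lg_model()


@pytest.fixture(scope="session")
def poisson():
    return poisson_model()


@pytest.fixture(scope="session")
def gamma4():
    return GammaRates(alpha=0.5, n_categories=4)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture()
def quartet_tree():
    return PhyloTree.from_newick("((A:1,B:2):3,(C:4,D:5):6);")
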