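import numpy as np
import pytest

from hylocomp.phylo import PhyloTree, vcv_from_tree
from hylocomp.simulate import reference_tree, simulate_tree


@pytest.fixture(scope="session")
def three_tip_tree():
    return PhyloTree.from_newick_string("((A:1,B:1):1,C:2);")


@pytest.fixture(scope="session")
def ref_tree():
    return reference_tree()


@pytest.fixture(scope="session")
def ref_cov(ref_tree):
    return vcv_from_tree(ref_tree)


@pytest.fixture(scope="session")
def yule20():
    return simulate_tree(20, seed=42)


@pytest.fixture(scope="session")
def yule20_cov(yule20):
    return vcv_from_tree(yule20)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
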