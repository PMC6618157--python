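import numpy as np
import pytest

from cophylokit.treecore import parse_newick
from cophylokit.fixtures import HostTreeSpec, surrogate_host_tree

from oracles import enumerate_topologies


@pytest.fixture(scope="session")
def host10():
    """A 10-tip ultrametric surrogate host tree, root age 500 Ma."""
    return surrogate_host_tree(HostTreeSpec(n_tips=10, root_age=500.0, seed=11))


@pytest.fixture(scope="session")
def host20():
    """A 20-tip ultrametric surrogate host tree, root age 500 Ma."""
    return surrogate_host_tree(HostTreeSpec(n_tips=20, root_age=500.0, seed=7))


@pytest.fixture(scope="session")
def topologies4():
    """All 15 rooted binary labeled topologies on 4 tips, unit lengths."""
    return enumerate_topologies(list("ABCD"))


def random_lengths(tree, rng, low=0.1, high=2.0):
    out = tree.copy()
    for node in out.branches():
        node.length = float(rng.uniform(low, high))
    return out


def random_tree(labels, rng, low=0.1, high=2.0):
    """A uniformly chosen rooted binary topology with random branch lengths."""
    tops = enumerate_topologies(labels)
    tree = tops[int(rng.integers(len(tops)))]
    return random_lengths(tree, rng, low, high)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def t(newick, allow_unary=False):
    return parse_newick(newick, allow_unary=allow_unary)
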