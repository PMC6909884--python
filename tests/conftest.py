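import random

import pytest

from frinet import (
    ClusterSet,
    PhyloNetwork,
    five_taxon_example,
    micro_example,
    ten_taxon_example,
)


@pytest.fixture
def micro() -> ClusterSet:
    return micro_example()


@pytest.fixture
def ex5() -> ClusterSet:
    return five_taxon_example()


@pytest.fixture
def ex10() -> ClusterSet:
    return ten_taxon_example()


@pytest.fixture
def rng() -> random.Random:
    return random.Random(1234)


def one_gall(labels=("1", "2", "3")) -> PhyloNetwork:
    """Single-reticulation gall: the middle label hangs below a reticulation
    whose parents sit on the pendant paths of the outer two labels."""
    a, b, c = labels
    n = PhyloNetwork()
    root = n.new_node()
    pa, pc = n.new_node(), n.new_node()
    ret = n.new_node()
    la, lb, lc = n.new_node(a), n.new_node(b), n.new_node(c)
    n.add_edge(root, pa)
    n.add_edge(root, pc)
    n.add_edge(pa, la)
    n.add_edge(pa, ret)
    n.add_edge(pc, ret)
    n.add_edge(pc, lc)
    n.add_edge(ret, lb)
    return n


def two_gall_chain() -> PhyloNetwork:
    """Two independent single-reticulation galls joined by a cut edge:
    total reticulation number 2 but level 1."""
    n = PhyloNetwork()
    root = n.new_node()
    upper = one_gall(("1", "2", "3"))
    lower = one_gall(("4", "5", "6"))
    mapping = {}
    for sub in (upper, lower):
        for v in sub.nodes():
            mapping[(id(sub), v)] = n.new_node(label=sub.label(v))
        for u, v in sub.edges():
            n.add_edge(mapping[(id(sub), u)], mapping[(id(sub), v)])
    n.add_edge(root, mapping[(id(upper), upper.root)])
    n.add_edge(root, mapping[(id(lower), lower.root)])
    # make the root binary-ish by hanging an outgroup leaf
    n.add_edge(root, n.new_node(label="7"))
    return n
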