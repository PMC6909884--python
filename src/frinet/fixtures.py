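"""Synthetic inputs: random gene trees perturbed by subtree transfers.

Incompatible cluster sets arise in practice when gene trees disagree because
of reticulate events.  The generator emulates that directly: it draws one
random rooted binary tree and derives each further tree by a number of
random subtree-prune-and-regraft (SPR) moves, the tree-space signature of a
transfer event.  The union of the trees' cluster sets is then incompatible
with probability approaching one as the number of moves grows.  Output is
deterministic for a fixed seed.
"""

from __future__ import annotations

import random
from dataclasses import dataclass

from .clusters import ClusterSet
from .network import PhyloNetwork, clusters_from_tree

__all__ = [
    "FixtureSpec",
    "make_fixture",
    "random_laminar_family",
    "random_tree",
    "spr_move",
    "union_clusters",
]


@dataclass(frozen=True)
class FixtureSpec:
    """Recipe for one synthetic input: taxon count, number of gene trees,
    SPR moves applied per derived tree, and the random seed."""

    taxa: int
    trees: int = 2
    moves: int = 1
    seed: int = 0


def random_tree(labels: list[str], rng: random.Random) -> PhyloNetwork:
    """Uniform-attachment random rooted binary tree on the given labels."""
    if len(labels) < 2:
        raise ValueError("need at least two taxa")
    t = PhyloNetwork()
    root = t.new_node()
    t.add_edge(root, t.new_node(label=labels[0]))
    t.add_edge(root, t.new_node(label=labels[1]))
    for lab in labels[2:]:
        u, v = rng.choice(t.edges())
        s = t.subdivide(u, v)
        t.add_edge(s, t.new_node(label=lab))
    return t


def spr_move(t: PhyloNetwork, rng: random.Random) -> PhyloNetwork:
    """One random subtree-prune-and-regraft move (returns a new tree)."""
    t = t.copy()
    root = t.root
    n_leaves = len(t.leaves())
    prunable = [(u, v) for u, v in t.edges()
                if len(t.descendant_leaves(v)) <= n_leaves - 2]
    u, v = rng.choice(prunable)
    t.remove_edge(u, v)
    # suppress the now-degree-two attachment node
    if u == root:
        (child,) = t.children(u)
        t.remove_node(u)
        remaining_root = child
    else:
        (parent,) = t.parents(u)
        (child,) = t.children(u)
        t.remove_node(u)
        t.add_edge(parent, child)
        remaining_root = root
    import networkx as nx

    pruned = nx.descendants(t.g, v) | {v}
    targets = [(a, b) for a, b in t.edges() if b not in pruned and a not in pruned]
    targets.append(None)  # regraft above the root
    choice = rng.choice(targets)
    if choice is None:
        new_root = t.new_node()
        t.add_edge(new_root, remaining_root)
        t.add_edge(new_root, v)
    else:
        s = t.subdivide(*choice)
        t.add_edge(s, v)
    t.validate()
    return t


def make_fixture(spec: FixtureSpec) -> list[PhyloNetwork]:
    """Generate the gene trees of a fixture; deterministic per seed."""
    if spec.taxa < 4:
        raise ValueError("fixtures need at least four taxa")
    rng = random.Random(spec.seed)
    labels = [str(i) for i in range(1, spec.taxa + 1)]
    base = random_tree(labels, rng)
    trees = [base]
    for _ in range(spec.trees - 1):
        t = base
        for _ in range(spec.moves):
            t = spr_move(t, rng)
        trees.append(t)
    return trees


def union_clusters(trees: list[PhyloNetwork]) -> ClusterSet:
    """Union of the trees' cluster sets (the builder's input), in tree order."""
    orders = []
    taxa: dict[str, None] = {}
    for t in trees:
        cs = clusters_from_tree(t)
        orders.extend(cs.cluster_orders)
        for x in cs.taxa:
            taxa.setdefault(x, None)
    return ClusterSet(orders, universe=list(taxa))


def random_laminar_family(n_taxa: int, rng: random.Random) -> ClusterSet:
    """A random compatible (laminar) cluster family: the edge clusters of a
    random tree, non-trivial part only."""
    labels = [str(i) for i in range(1, n_taxa + 1)]
    t = random_tree(labels, rng)
    cs = clusters_from_tree(t)
    return ClusterSet([o for o in cs.cluster_orders if len(o) >= 2],
                      universe=cs.taxa)
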