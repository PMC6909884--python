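"""Tripartitions of network edges and the tripartition distance.

For an edge ``e = (u, v)`` the taxa split three ways: the *strict* part
(descendants of ``v`` for which ``v`` lies on every root path — ``v`` is
their stable ancestor), the *loose* part (descendants reachable from ``v``
only through some switched path, i.e. ``v`` is not stable over them), and
the *outside* part (non-descendants).  The three blocks partition the
universe.  ``Θ(N)`` collects the tripartitions of all edges with set
semantics, and the distance between two networks on the same taxa is half
the symmetric difference ``|Θ(N1) Δ Θ(N2)| / 2`` — a multiple of 0.5 that is
zero exactly for equal tripartition sets.  On trees every loose part is
empty and the distance reduces to half the symmetric difference of the
cluster sets.
"""

from __future__ import annotations

from typing import NamedTuple

import networkx as nx

from .network import PhyloNetwork

__all__ = [
    "Tripartition",
    "is_stable_ancestor",
    "tripartition_distance",
    "tripartitions",
]


class Tripartition(NamedTuple):
    strict: frozenset
    loose: frozenset
    outside: frozenset


def is_stable_ancestor(n: PhyloNetwork, u: int, v: int) -> bool:
    """True iff every directed root-to-``v`` path passes through ``u``."""
    if u == v:
        return True
    root = n.root
    if v == root:
        return False
    if u == root:
        return True
    g = n.g.copy()
    g.remove_node(u)
    return v not in nx.descendants(g, root)


def _stable_leaf_sets(n: PhyloNetwork) -> dict[int, frozenset]:
    """For each node v: the leaf labels over which v is a stable ancestor."""
    root = n.root
    leaves = {w: n.label(w) for w in n.leaves()}
    out: dict[int, frozenset] = {}
    for v in n.nodes():
        if v == root:
            out[v] = frozenset(leaves.values())
            continue
        g = n.g.copy()
        g.remove_node(v)
        reach = nx.descendants(g, root) | {root}
        cut = {lab for w, lab in leaves.items() if w == v or w not in reach}
        out[v] = frozenset(cut)
    return out


def tripartitions(n: PhyloNetwork) -> frozenset[Tripartition]:
    """The tripartition set ``Θ(N)``: one per edge, duplicates merged."""
    n.validate()
    universe = n.leaf_labels()
    stable = _stable_leaf_sets(n)
    out = set()
    for _, v in n.edges():
        desc = n.descendant_leaves(v)
        strict = stable[v] & desc
        out.add(Tripartition(strict, desc - strict, universe - desc))
    return frozenset(out)


def tripartition_distance(n1: PhyloNetwork, n2: PhyloNetwork) -> float:
    """Half the symmetric difference of the two tripartition sets."""
    if n1.leaf_labels() != n2.leaf_labels():
        raise ValueError("networks are on different taxon sets")
    t1, t2 = tripartitions(n1), tripartitions(n2)
    return len(t1 ^ t2) / 2.0
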