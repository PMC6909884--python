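"""Soft-wired cluster enumeration and representation checking.

A network *displays* a cluster in the soft-wired sense when some *switching*
— a choice of one incoming edge per reticulation, all others switched off —
makes the cluster equal to the descendant leaf set of some node.  The full
soft-wired cluster set is the union over all switchings; for a tree (no
reticulations, a single switching) it coincides with the per-edge clusters.

Clusters displayed beyond those of the input set are *redundant*; their count
``c``, together with the reticulation number ``r``, measures how much extra
(unsupported) history a constructed network asserts.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

from .clusters import ClusterSet
from .errors import ResourceError
from .network import PhyloNetwork

__all__ = [
    "SoftwiredResult",
    "redundant_cluster_count",
    "represents",
    "softwired_clusters",
]


@dataclass(frozen=True)
class SoftwiredResult:
    """All clusters displayed by a network plus the number of switchings used."""

    clusters: ClusterSet
    switch_count: int


def _display_sets(n: PhyloNetwork, cap: int) -> tuple[set[frozenset], int]:
    rets = n.reticulations()
    if len(rets) > cap:
        raise ResourceError(
            f"{len(rets)} reticulations exceed the enumeration cap {cap}")
    g = n.g
    choice_lists = [[(p, v) for p in n.parents(v)] for v in rets]
    order = list(reversed(list(_topological(n))))  # children before parents
    out: set[frozenset] = set()
    count = 0
    for choice in itertools.product(*choice_lists):
        count += 1
        on = {v: p for p, v in choice}
        desc: dict[int, frozenset] = {}
        for v in order:
            if g.out_degree(v) == 0:
                desc[v] = frozenset((n.label(v),))
            else:
                acc = set()
                for w in g.successors(v):
                    if w in on and on[w] != v:
                        continue  # switched-off reticulation edge
                    acc |= desc[w]
                desc[v] = frozenset(acc)
        out.update(desc.values())
    return out, count


def _topological(n: PhyloNetwork):
    import networkx as nx

    return nx.topological_sort(n.g)


def softwired_clusters(n: PhyloNetwork, cap: int = 20) -> SoftwiredResult:
    """Union of displayed clusters over every reticulation switching.

    The empty set and the full leaf set are dropped; singletons are retained
    (they are trivial in the :class:`~frinet.clusters.ClusterSet` sense).
    Raises :class:`~frinet.errors.ResourceError` when the reticulation count
    exceeds ``cap``.
    """
    sets, count = _display_sets(n, cap)
    uni = n.leaf_labels()
    taxa = [n.label(v) for v in n.leaves()]
    kept = sorted((s for s in sets if s and s != uni),
                  key=lambda s: (len(s), sorted(s)))
    cs = ClusterSet((tuple(sorted(s)) for s in kept), universe=taxa)
    return SoftwiredResult(cs, count)


def represents(n: PhyloNetwork, y: ClusterSet, cap: int = 20) -> bool:
    """True iff every (proper) cluster of ``y`` is displayed by ``n``.

    The universes must agree; clusters equal to the whole universe are
    represented by every network and are ignored.
    """
    if n.leaf_labels() != y.universe:
        raise ValueError("network leaves and cluster universe differ")
    sets, _ = _display_sets(n, cap)
    return all(c in sets for c in y.clusters if c != y.universe)


def redundant_cluster_count(n: PhyloNetwork, y: ClusterSet, cap: int = 20) -> int:
    """Number of non-trivial proper clusters displayed by ``n`` but absent
    from ``y``.  Requires that ``n`` represents ``y``."""
    if n.leaf_labels() != y.universe:
        raise ValueError("network leaves and cluster universe differ")
    sets, _ = _display_sets(n, cap)
    missing = [c for c in y.clusters if c != y.universe and c not in sets]
    if missing:
        raise ValueError(f"network does not represent {len(missing)} input clusters")
    uni = y.universe
    extra = {s for s in sets if len(s) >= 2 and s != uni}
    return len(extra - set(y.nontrivial))
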