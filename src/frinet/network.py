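"""Rooted phylogenetic trees and networks as leaf-labeled DAGs.

A :class:`PhyloNetwork` is a rooted DAG with a unique in-degree-0 root,
bijectively leaf-labeled sinks, and *reticulation* nodes of in-degree >= 2.
Its reticulation number is ``|E| - |V| + 1``, equivalently the sum of
``indeg(v) - 1`` over non-root nodes; the *level* is the maximum reticulation
number over biconnected components of the underlying undirected graph.
A rooted tree is simply a network with reticulation number zero.
"""

from __future__ import annotations

import itertools
from typing import Iterable, Sequence

import networkx as nx

from .clusters import ClusterSet, is_compatible_set

__all__ = [
    "PhyloNetwork",
    "canonical_form",
    "clusters_from_tree",
    "is_simple_level_k",
    "level",
    "reticulation_number",
    "tree_from_compatible_clusters",
]


class PhyloNetwork:
    """Mutable rooted DAG with labeled leaves.

    Nodes are opaque integers; leaves carry a ``label``.  Child order is the
    edge-insertion order, which the builder keeps aligned with the taxon
    first-encounter order so that traversals are deterministic.
    """

    def __init__(self):
        self.g = nx.DiGraph()
        self._next = 0

    # -- construction --------------------------------------------------

    def new_node(self, label: str | None = None) -> int:
        v = self._next
        self._next += 1
        self.g.add_node(v, label=label)
        return v

    def add_edge(self, u: int, v: int) -> None:
        self.g.add_edge(u, v)

    def remove_edge(self, u: int, v: int) -> None:
        self.g.remove_edge(u, v)

    def remove_node(self, v: int) -> None:
        self.g.remove_node(v)

    def subdivide(self, u: int, v: int) -> int:
        """Replace edge (u, v) by u -> s -> v and return s."""
        s = self.new_node()
        self.g.remove_edge(u, v)
        self.g.add_edge(u, s)
        self.g.add_edge(s, v)
        return s

    def copy(self) -> "PhyloNetwork":
        n = PhyloNetwork()
        n.g = self.g.copy()
        n._next = self._next
        return n

    # -- queries -------------------------------------------------------

    @property
    def root(self) -> int:
        roots = [v for v in self.g if self.g.in_degree(v) == 0]
        if len(roots) != 1:
            raise ValueError(f"network has {len(roots)} roots")
        return roots[0]

    def label(self, v: int) -> str | None:
        return self.g.nodes[v].get("label")

    def set_label(self, v: int, label: str | None) -> None:
        self.g.nodes[v]["label"] = label

    def children(self, v: int) -> list[int]:
        return list(self.g.successors(v))

    def parents(self, v: int) -> list[int]:
        return list(self.g.predecessors(v))

    def nodes(self) -> list[int]:
        return list(self.g.nodes)

    def edges(self) -> list[tuple[int, int]]:
        return list(self.g.edges)

    def leaves(self) -> list[int]:
        return [v for v in self.g if self.g.out_degree(v) == 0]

    def leaf_labels(self) -> frozenset:
        return frozenset(self.label(v) for v in self.leaves())

    def reticulations(self) -> list[int]:
        return [v for v in self.g if self.g.in_degree(v) >= 2]

    def is_tree(self) -> bool:
        return reticulation_number(self) == 0

    def descendant_leaves(self, v: int) -> frozenset:
        """Hard-wired descendant leaf labels of ``v`` (including ``v`` itself)."""
        out = set()
        if self.g.out_degree(v) == 0:
            out.add(self.label(v))
        for w in nx.descendants(self.g, v):
            if self.g.out_degree(w) == 0:
                out.add(self.label(w))
        return frozenset(out)

    def dfs_edges(self) -> list[tuple[int, int]]:
        """Edges in depth-first discovery order from the root, children in
        insertion order; reticulations are entered once."""
        out, seen = [], set()

        def walk(v):
            for w in self.children(v):
                out.append((v, w))
                if w not in seen:
                    seen.add(w)
                    walk(w)

        walk(self.root)
        return out

    def validate(self) -> None:
        g = self.g
        if not nx.is_directed_acyclic_graph(g):
            raise ValueError("network contains a directed cycle")
        root = self.root
        if set(nx.descendants(g, root)) | {root} != set(g):
            raise ValueError("not all nodes are reachable from the root")
        labels = [self.label(v) for v in self.leaves()]
        if None in labels:
            raise ValueError("unlabeled leaf")
        if len(labels) != len(set(labels)):
            raise ValueError("duplicate leaf labels")

    def __repr__(self) -> str:
        return (f"PhyloNetwork({self.g.number_of_nodes()} nodes, "
                f"{self.g.number_of_edges()} edges, "
                f"r={reticulation_number(self)})")


def reticulation_number(n: PhyloNetwork) -> int:
    """``|E| - |V| + 1`` for a rooted connected DAG."""
    return n.g.number_of_edges() - n.g.number_of_nodes() + 1


def level(n: PhyloNetwork) -> int:
    """Maximum reticulation number over undirected biconnected components."""
    und = n.g.to_undirected()
    best = 0
    for comp in nx.biconnected_components(und):
        if len(comp) < 3:
            continue
        sub = n.g.subgraph(comp)
        best = max(best, sub.number_of_edges() - len(comp) + 1)
    return best


def is_simple_level_k(n: PhyloNetwork, k: int) -> bool:
    """A network is simple level-<=k when it has reticulation number <= k and
    no internal cut node (leaves and their pendant edges are exempt, since a
    pendant attachment is always an articulation point)."""
    if reticulation_number(n) > k:
        return False
    und = n.g.to_undirected()
    und.remove_nodes_from([v for v in n.g if n.g.out_degree(v) == 0])
    if und.number_of_nodes() <= 2:
        return True
    if not nx.is_connected(und):
        return False
    return not any(True for _ in nx.articulation_points(und))


# -- canonical form ------------------------------------------------------


def _unfolded(n: PhyloNetwork) -> dict[int, str]:
    """Tree-unfolding encoding per node (shared subgraphs repeated)."""
    memo: dict[int, str] = {}

    def enc(v):
        if v not in memo:
            kids = n.children(v)
            if not kids:
                memo[v] = n.label(v)
            else:
                memo[v] = "(" + ",".join(sorted(enc(w) for w in kids)) + ")"
        return memo[v]

    enc(n.root)
    return memo


def canonical_form(n: PhyloNetwork) -> str:
    """Label-aware canonical token: equal for two networks iff they are
    isomorphic as leaf-labeled rooted DAGs.

    Reticulation nodes are numbered by iteratively refining an unfolding
    encoding, then every node is encoded with reticulations as ``#H<i>``
    stubs whose definitions are appended; the token is invariant under node
    renumbering and edge-storage order.
    """
    unfolded = _unfolded(n)
    rets = sorted(n.reticulations(), key=lambda v: unfolded[v])
    ids = {}
    # refine: re-rank using encodings that expose already-assigned hybrid ids
    for _ in range(max(1, len(rets))):
        ids = {v: i for i, v in enumerate(rets)}
        memo: dict[int, str] = {}

        def enc(v, _ids=ids, _memo=memo):
            if v in _memo:
                return _memo[v]
            kids = n.children(v)
            if not kids:
                body = n.label(v)
            else:
                body = "(" + ",".join(sorted(enc(w, _ids, _memo)
                                             for w in kids)) + ")"
            if v in _ids:
                body += f"#H{_ids[v]}"
            _memo[v] = body
            return _memo[v]

        enc(n.root)
        new_order = sorted(rets, key=lambda v: memo[v])
        if new_order == rets:
            break
        rets = new_order

    ids = {v: i for i, v in enumerate(rets)}
    memo2: dict[int, str] = {}

    def enc2(v):
        if v in ids:
            return f"#H{ids[v]}"
        if v not in memo2:
            kids = n.children(v)
            if not kids:
                memo2[v] = n.label(v)
            else:
                memo2[v] = "(" + ",".join(sorted(enc2(w) for w in kids)) + ")"
        return memo2[v]

    parts = [enc2(n.root)]
    for v in rets:
        kids = n.children(v)
        if kids:
            body = "(" + ",".join(sorted(enc2(w) for w in kids)) + ")"
        else:
            body = n.label(v) or ""
        parts.append(f"H{ids[v]}={body}")
    return ";".join(parts)


def clusters_from_tree(t: PhyloNetwork) -> ClusterSet:
    """One cluster per tree edge: the leaf set below the edge's child.

    The full leaf set is dropped and duplicates are merged; singleton
    clusters (pendant edges) are retained and count as trivial.  Taxa are
    ordered by the left-to-right leaf order of the tree.
    """
    t.validate()
    if not t.is_tree():
        raise ValueError("input is not a tree")
    leaf_order: list[str] = []

    def walk(v):
        if not t.children(v):
            leaf_order.append(t.label(v))
        for w in t.children(v):
            walk(w)

    walk(t.root)
    idx = {lab: i for i, lab in enumerate(leaf_order)}
    uni = frozenset(leaf_order)
    orders = []
    for _, v in t.dfs_edges():
        c = t.descendant_leaves(v)
        if c != uni:
            orders.append(tuple(sorted(c, key=idx.__getitem__)))
    return ClusterSet(orders, universe=leaf_order)


# -- trees from compatible clusters --------------------------------------


def label_sort_key(label: str):
    """Natural ordering for taxon labels: numeric labels first, by value."""
    return (0, int(label), "") if label.isdigit() else (1, 0, label)


def _cluster_sort_key(c):
    return tuple(sorted(label_sort_key(t) for t in c))


def tree_from_compatible_clusters(y: ClusterSet) -> PhyloNetwork:
    """Unique rooted tree whose non-trivial edge clusters are exactly the
    non-trivial clusters of the compatible (laminar) family ``y``.

    The tree is the Hasse diagram of the family under inclusion with the
    universe as root and every taxon as a leaf.  Children are stored in the
    natural order of their label sets, so the tree object — including its
    traversal order — depends only on the cluster set, not on the order its
    clusters or taxa were listed in.
    """
    if not is_compatible_set(y):
        raise ValueError("cluster set is incompatible; no tree exists")
    uni = y.universe
    groups = [c for c in y.nontrivial if c != uni]
    groups = sorted(set(groups), key=lambda c: (-len(c), _cluster_sort_key(c)))

    n = PhyloNetwork()
    root = n.new_node()
    node_of: dict[frozenset, int] = {uni: root}
    # parents: smallest strict superset; groups are scanned largest-first so
    # the parent already exists when a child is attached
    ordered: dict[int, list[tuple]] = {root: []}
    for c in groups:
        parent = uni
        for d in groups:
            if c < d and d < parent:
                parent = d
        v = n.new_node()
        node_of[c] = v
        ordered.setdefault(v, [])
        ordered[node_of[parent]].append((_cluster_sort_key(c), v))
    for t in y.taxa:
        parent = uni
        for d in groups:
            if t in d and d < parent:
                parent = d
        leaf = n.new_node(label=t)
        ordered[node_of[parent]].append((_cluster_sort_key((t,)), leaf))
    for v, kids in ordered.items():
        for _, w in sorted(kids):
            n.add_edge(v, w)
    return n
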