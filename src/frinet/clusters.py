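"""Cluster-set data model for rooted phylogenetic network construction.

A *cluster* is a non-empty proper subset of a taxon universe ``X``; it is
non-trivial when it has at least two members.  Two clusters are *compatible*
when they are disjoint or nested; a cluster set is compatible iff every pair
is, which holds exactly when the set is realizable by a rooted tree.  The
*incompatibility graph* ``IG(Y)`` has the non-trivial clusters of ``Y`` as
nodes and an edge between every incompatible pair; its edge count ``d(Y)`` is
the incompatibility degree of the set.

Two per-taxon statistics drive the network builder:

* frequency ``f(x)`` — the number of clusters containing ``x``;
* incompatibility degree ``d(x) = d(Y) - d(Y with x deleted)`` — how much of
  the conflict in ``Y`` disappears when ``x`` is deleted from every cluster.

The module also implements *ST-sets* (strict tree sets): taxon subsets that
are compatible with every cluster and internally tree-like, which are
collapsed into single meta-taxa before taxon removal.  Meta-taxon labels are
reserved tokens starting with ``&`` and encode their base taxa, so a collapse
is always invertible.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import networkx as nx

__all__ = [
    "ClusterSet",
    "CollapseEntry",
    "CollapseMap",
    "collapse_maximal_st_sets",
    "expand",
    "incompatibility_components",
    "incompatibility_degree",
    "incompatibility_graph",
    "is_compatible_pair",
    "is_compatible_set",
    "is_st_set",
    "meta_base",
    "meta_label",
    "restrict_remove",
    "restrict_to",
    "taxon_frequency",
    "taxon_incompatibility_degree",
]

META_PREFIX = "&"
_FORBIDDEN = set(" \t\n(),:;")


def _check_label(label: str) -> str:
    if not label or any(ch in _FORBIDDEN for ch in label):
        raise ValueError(f"invalid taxon label: {label!r}")
    return label


def meta_label(members: Iterable[str]) -> str:
    """Reserved, self-describing label for the meta-taxon collapsing *members*.

    The label records the sorted base taxa, so nested collapses always produce
    distinct, collision-free tokens that never clash with user labels (user
    labels may not start with ``&``).
    """
    base = sorted(set().union(*(meta_base(m) for m in members)))
    return META_PREFIX + "+".join(base)


def meta_base(label: str) -> frozenset[str]:
    """Base (user-level) taxa represented by a possibly-meta label."""
    if label.startswith(META_PREFIX):
        return frozenset(label[len(META_PREFIX):].split("+"))
    return frozenset((label,))


class ClusterSet:
    """An ordered family of distinct clusters over a taxon universe.

    Clusters are stored with set semantics (duplicates merged, first
    occurrence kept) but both the cluster order and the per-cluster member
    order are preserved: the *first-encounter order of taxa* derived from
    them drives every tie-break downstream, which is what makes the
    input-order-dependence of the construction observable at all.

    Parameters
    ----------
    clusters:
        Iterable of taxon-label sequences.  Order matters.
    universe:
        Optional explicit taxon sequence.  Taxa seen in clusters but missing
        here raise; taxa listed here but absent from every cluster are kept
        at the end of the first-encounter order.
    """

    __slots__ = ("_orders", "_clusters", "_taxa", "_index", "_universe")

    def __init__(self, clusters: Iterable[Sequence[str]] = (),
                 universe: Sequence[str] | None = None):
        seen_clusters: dict[frozenset, tuple] = {}
        taxa: dict[str, None] = {}
        for members in clusters:
            members = tuple(members)
            if not members:
                raise ValueError("clusters must be non-empty")
            fs = frozenset(members)
            if fs not in seen_clusters:
                seen_clusters[fs] = members
            for t in members:
                if t not in taxa:
                    taxa[_check_label(t)] = None
        if universe is not None:
            uni = [_check_label(t) for t in universe]
            missing = set(taxa) - set(uni)
            if missing:
                raise ValueError(f"cluster taxa outside universe: {sorted(missing)}")
            for t in uni:
                if t not in taxa:
                    taxa[t] = None
        self._orders = tuple(seen_clusters.values())
        self._clusters = tuple(seen_clusters)
        self._taxa = tuple(taxa)
        self._index = {t: i for i, t in enumerate(self._taxa)}
        self._universe = frozenset(self._taxa)

    # -- basic views ---------------------------------------------------

    @property
    def clusters(self) -> tuple[frozenset, ...]:
        return self._clusters

    @property
    def cluster_orders(self) -> tuple[tuple[str, ...], ...]:
        """Clusters with their original member order (for permutation runs)."""
        return self._orders

    @property
    def taxa(self) -> tuple[str, ...]:
        """Universe in first-encounter order."""
        return self._taxa

    @property
    def universe(self) -> frozenset:
        return self._universe

    @property
    def nontrivial(self) -> tuple[frozenset, ...]:
        return tuple(c for c in self._clusters if len(c) >= 2)

    def nontrivial_set(self) -> "ClusterSet":
        """The sub-family of non-trivial clusters over the same universe."""
        return ClusterSet((o for o in self._orders if len(o) >= 2),
                          universe=self._taxa)

    def index(self, taxon: str) -> int:
        try:
            return self._index[taxon]
        except KeyError:
            raise ValueError(f"unknown taxon: {taxon!r}") from None

    def sort_key(self, cluster: Iterable[str]):
        """Deterministic ordering key for a taxon subset: earliest member first."""
        return tuple(sorted(self._index[t] for t in cluster))

    def __len__(self) -> int:
        return len(self._clusters)

    def __iter__(self) -> Iterator[frozenset]:
        return iter(self._clusters)

    def __contains__(self, cluster) -> bool:
        return frozenset(cluster) in set(self._clusters)

    def __eq__(self, other) -> bool:
        if not isinstance(other, ClusterSet):
            return NotImplemented
        return (self._universe == other._universe
                and set(self._clusters) == set(other._clusters))

    def __hash__(self):
        return hash((self._universe, frozenset(self._clusters)))

    def __repr__(self) -> str:
        shown = ", ".join("{" + ",".join(o) + "}" for o in self._orders[:6])
        more = "" if len(self._orders) <= 6 else f", … ({len(self._orders)} total)"
        return f"ClusterSet([{shown}{more}] on {len(self._taxa)} taxa)"

    def replace_clusters(self, orders: Iterable[Sequence[str]],
                         universe: Sequence[str] | None = None) -> "ClusterSet":
        return ClusterSet(orders, universe=self._taxa if universe is None else universe)


# -- compatibility ------------------------------------------------------


def is_compatible_pair(c1: Iterable[str], c2: Iterable[str]) -> bool:
    """True iff the two clusters are disjoint or nested."""
    s1, s2 = frozenset(c1), frozenset(c2)
    return s1.isdisjoint(s2) or s1 <= s2 or s2 <= s1


def is_compatible_set(y: ClusterSet) -> bool:
    """True iff every unordered pair of clusters in ``y`` is compatible."""
    clusters = y.nontrivial
    return all(is_compatible_pair(a, b)
               for a, b in itertools.combinations(clusters, 2))


def incompatibility_graph(y: ClusterSet) -> nx.Graph:
    """Graph on the non-trivial clusters of ``y``; edges join incompatible pairs."""
    g = nx.Graph()
    clusters = y.nontrivial
    g.add_nodes_from(clusters)
    for a, b in itertools.combinations(clusters, 2):
        if not is_compatible_pair(a, b):
            g.add_edge(a, b)
    return g


def incompatibility_degree(y: ClusterSet) -> int:
    """``d(Y)``: the number of edges of the incompatibility graph."""
    return incompatibility_graph(y).number_of_edges()


def incompatibility_components(y: ClusterSet) -> list[ClusterSet]:
    """Non-trivial connected components of ``IG(y)``.

    A component is non-trivial when it contains at least one incompatible
    pair (isolated compatible clusters are not returned).  Components are
    ordered by the earliest taxon they contain; cluster order within a
    component follows the order in ``y``.
    """
    g = incompatibility_graph(y)
    comps = []
    for nodes in nx.connected_components(g):
        if len(nodes) < 2:
            continue
        orders = [o for o in y.cluster_orders if frozenset(o) in nodes]
        comps.append(y.replace_clusters(
            orders, universe=[t for t in y.taxa
                              if any(t in c for c in nodes)]))
    comps.sort(key=lambda cs: min(y.index(t) for t in cs.universe))
    return comps


# -- per-taxon statistics ------------------------------------------------


def taxon_frequency(y: ClusterSet, x: str) -> int:
    """``f(x)``: the number of stored clusters of ``y`` containing ``x``."""
    y.index(x)
    return sum(1 for c in y.clusters if x in c)


def taxon_incompatibility_degree(y: ClusterSet, x: str,
                                 method: str = "shared") -> int:
    """``d(x)``: how much of the incompatibility of ``Y`` involves taxon ``x``.

    The default ``"shared"`` semantics counts the incompatibility-graph edges
    ``(C1, C2)`` with ``x ∈ C1 ∩ C2`` — the taxa shared by conflicting
    clusters, which are exactly the ones a reticulation can disentangle.  On
    the two-cluster worked set ``{{1,2},{2,3}}`` this gives ``d = (0, 1, 0)``.

    ``method="removal"`` instead returns ``d(Y) - d(Y')`` where ``Y'``
    deletes ``x`` from every cluster.  The two differ when deleting ``x``
    collapses a conflicting cluster to a singleton: the removal reading also
    credits ``x`` with edges that disappear only because a node of the graph
    became trivial (there, ``d = (1, 1, 1)``).
    """
    y.index(x)
    if method == "shared":
        g = incompatibility_graph(y)
        return sum(1 for c1, c2 in g.edges if x in c1 and x in c2)
    if method == "removal":
        return incompatibility_degree(y) - incompatibility_degree(
            restrict_remove(y, {x}))
    raise ValueError(f"unknown method: {method!r}")


# -- restriction ---------------------------------------------------------


def restrict_remove(y: ClusterSet, s: Iterable[str]) -> ClusterSet:
    """Delete the taxa of ``s`` from every cluster.

    Clusters that become empty are dropped, duplicates are merged, and the
    universe shrinks by ``s``.
    """
    s = frozenset(s)
    extra = s - y.universe
    if extra:
        raise ValueError(f"taxa not in universe: {sorted(extra)}")
    orders = []
    for o in y.cluster_orders:
        kept = tuple(t for t in o if t not in s)
        if kept:
            orders.append(kept)
    return ClusterSet(orders, universe=[t for t in y.taxa if t not in s])


def restrict_to(y: ClusterSet, s: Iterable[str]) -> ClusterSet:
    """Intersect every cluster with ``s`` (dropping empties); universe becomes ``s``."""
    s = frozenset(s)
    orders = []
    for o in y.cluster_orders:
        kept = tuple(t for t in o if t in s)
        if kept:
            orders.append(kept)
    return ClusterSet(orders, universe=[t for t in y.taxa if t in s])


# -- ST-sets -------------------------------------------------------------


def is_st_set(y: ClusterSet, s: Iterable[str]) -> bool:
    """Strict tree set test.

    ``s`` (with at least two members) is an ST-set of ``y`` iff ``s`` is
    compatible with every cluster of ``y`` and the restriction of ``y`` onto
    ``s`` (clusters intersected with ``s``) is itself compatible.
    """
    s = frozenset(s)
    if len(s) < 2:
        raise ValueError("an ST-set must contain at least two taxa")
    if not s <= y.universe:
        raise ValueError("ST-set candidate outside the universe")
    if any(not is_compatible_pair(s, c) for c in y.clusters):
        return False
    return is_compatible_set(restrict_to(y, s))


@dataclass(frozen=True)
class CollapseEntry:
    """One meta-taxon: its label, ordered members, and the clusters it absorbed."""

    label: str
    members: tuple[str, ...]
    inner: tuple[frozenset, ...] = ()


@dataclass
class CollapseMap:
    """Invertible record of ST-set collapses, in the order they were applied."""

    entries: list[CollapseEntry] = field(default_factory=list)

    def __bool__(self) -> bool:
        return bool(self.entries)

    def __len__(self) -> int:
        return len(self.entries)

    def labels(self) -> set[str]:
        return {e.label for e in self.entries}


def _collapse_pair(y: ClusterSet, s: frozenset) -> tuple[ClusterSet, CollapseEntry]:
    members = tuple(t for t in y.taxa if t in s)
    label = meta_label(members)
    inner = []
    orders = []
    for o in y.cluster_orders:
        fs = frozenset(o)
        if fs < s:
            inner.append(fs)
        elif fs == s:
            orders.append((label,))
        elif s <= fs:
            done = False
            new = []
            for t in o:
                if t in s:
                    if not done:
                        new.append(label)
                        done = True
                else:
                    new.append(t)
            orders.append(tuple(new))
        else:
            orders.append(o)
    new_taxa = []
    placed = False
    for t in y.taxa:
        if t in s:
            if not placed:
                new_taxa.append(label)
                placed = True
        else:
            new_taxa.append(t)
    return (ClusterSet(orders, universe=new_taxa),
            CollapseEntry(label, members, tuple(dict.fromkeys(inner))))


def collapse_maximal_st_sets(y: ClusterSet) -> tuple[ClusterSet, CollapseMap]:
    """Collapse every maximal ST-set of ``y`` into a fresh meta-taxon.

    Maximal ST-sets are grown by greedy pairwise agglomeration: whenever a
    pair of current (possibly meta) taxa forms an ST-set, it is merged, the
    earliest-encountered pair first.  A minimal non-trivial member of a
    laminar restriction always contains a mergeable pair, so the fixpoint of
    pair merges reaches the maximal ST-set partition.  The result contains
    no ST-set of size two or more, which makes the operation idempotent.
    """
    cur = y
    cmap = CollapseMap()
    progress = True
    while progress:
        progress = False
        taxa = cur.taxa
        for a, b in itertools.combinations(taxa, 2):
            pair = frozenset((a, b))
            if is_st_set(cur, pair):
                cur, entry = _collapse_pair(cur, pair)
                cmap.entries.append(entry)
                progress = True
                break
    return cur, cmap


def expand(y: ClusterSet, m: CollapseMap) -> ClusterSet:
    """Undo a collapse: meta-taxa are replaced by their members, absorbed
    clusters are restored.  Entries are unwound in reverse collapse order."""
    cur = y
    for entry in reversed(m.entries):
        if entry.label not in cur.universe:
            if any(entry.label in c for c in cur.clusters):  # pragma: no cover
                raise ValueError(f"inconsistent meta-taxon {entry.label!r}")
            continue
        orders = []
        for o in cur.cluster_orders:
            if o == (entry.label,):
                orders.append(entry.members)
            else:
                new = []
                for t in o:
                    if t == entry.label:
                        new.extend(entry.members)
                    else:
                        new.append(t)
                orders.append(tuple(new))
        for fs in entry.inner:
            orders.append(tuple(sorted(fs)))
        new_taxa = []
        for t in cur.taxa:
            if t == entry.label:
                new_taxa.extend(entry.members)
            else:
                new_taxa.append(t)
        cur = ClusterSet(orders, universe=new_taxa)
    return cur
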