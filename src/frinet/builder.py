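"""Network construction by taxon removal and reticulate reinsertion.

The builder turns an incompatible cluster set into a rooted network that
represents every input cluster in the soft-wired sense.  It follows the
classic four-step decomposition:

1. split the incompatibility graph into non-trivial connected components and
   collapse each component's maximal ST-sets into meta-taxa;
2. for each component, remove (meta-)taxa one at a time — re-collapsing after
   every removal — until the remainder is compatible, then rebuild a tree and
   re-add the removed taxa as children of new reticulation nodes, giving a
   simple network whose reticulation number equals the number of removals;
3. build a backbone tree for the clusters outside the components plus each
   component's taxon set and its unseparated subsets;
4. graft the simple networks onto the backbone and expand the meta-taxa.

Two removal strategies are provided.  *Cass mode* searches all removal
sequences depth-first in taxon encounter order and keeps the first network
found — faithful to the original algorithm, including its dependence on
input order.  *Frin mode* scores each taxon by ``s(x) = p·f(x) + q·d(x)``
(frequency and incompatibility degree), greedily removes the argmax for each
of the ten weightings ``p = 0.1 … 1.0`` (``q = 1 - p``), deduplicates the
resulting removal traces, builds one network per trace, and keeps the
candidate with the fewest reticulations, then fewest redundant clusters.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

from .clusters import (
    META_PREFIX,
    ClusterSet,
    CollapseMap,
    collapse_maximal_st_sets,
    incompatibility_components,
    is_compatible_set,
    meta_base,
    restrict_remove,
    taxon_frequency,
    taxon_incompatibility_degree,
)
from .errors import ResourceError
from .network import (
    PhyloNetwork,
    canonical_form,
    level,
    reticulation_number,
    tree_from_compatible_clusters,
)
from .softwired import redundant_cluster_count, represents

__all__ = [
    "BuildConfig",
    "Candidate",
    "RemovalStep",
    "RemovalTrace",
    "assemble",
    "backbone_tree",
    "build",
    "build_candidates",
    "cass_removal",
    "frin_removal",
    "reinsert",
    "score",
    "weight_pairs",
]


_log = logging.getLogger(__name__)


@dataclass(frozen=True)
class BuildConfig:
    """Tunable knobs of the construction search."""

    mode: str = "frin"
    max_k: int = 6
    weight_step: float = 0.1
    tie_break: str = "lexicographic"  # or "first-encounter"
    degree_method: str = "shared"  # d(x) semantics; see taxon_incompatibility_degree
    keep_placements: str = "first"  # "all": keep every distinct reinsertion per trace
    placement_cap: int = 256
    reticulation_cap: int = 20
    max_combinations: int = 1024


@dataclass(frozen=True)
class RemovalStep:
    """One removal round: the (meta-)taxon taken out and the collapse that
    followed, bracketed by the cluster sets before and after."""

    removed: str
    removed_base: frozenset
    before: ClusterSet
    collapse: CollapseMap
    after: ClusterSet


@dataclass(frozen=True)
class RemovalTrace:
    """Ordered removal rounds, with the (p, q) weighting that produced them
    (absent in Cass mode).  Traces compare equal when their removed-taxon
    sequences agree after expansion to base taxa."""

    steps: tuple[RemovalStep, ...]
    weights: tuple[float, float] | None = None

    def key(self) -> tuple[frozenset, ...]:
        return tuple(s.removed_base for s in self.steps)

    def final(self, initial: ClusterSet) -> ClusterSet:
        return self.steps[-1].after if self.steps else initial

    def __len__(self) -> int:
        return len(self.steps)


@dataclass(frozen=True)
class Candidate:
    """A constructed network with its quality statistics and provenance."""

    network: PhyloNetwork
    k: int
    r: int
    c: int
    level: int
    traces: tuple[RemovalTrace, ...]
    form: str = field(repr=False, default="")


def weight_pairs(step: float = 0.1) -> list[tuple[float, float]]:
    """The (p, q) weightings swept in Frin mode: ``p = step, 2·step, …, 1``
    with ``q = 1 - p``.  ``step`` must divide 1 evenly."""
    n = round(1.0 / step)
    if n <= 0 or abs(n * step - 1.0) > 1e-9:
        raise ValueError(f"step {step} does not divide 1 evenly")
    return [(round(i * step, 10), round(1.0 - i * step, 10))
            for i in range(1, n + 1)]


def score(y: ClusterSet, x: str, p: float, q: float,
          degree_method: str = "shared") -> float:
    """``s(x) = p·f(x) + q·d(x)`` on the cluster set ``y``."""
    return (p * taxon_frequency(y, x)
            + q * taxon_incompatibility_degree(y, x, method=degree_method))


def _pick_removal(cur: ClusterSet, p: float, q: float, cfg: BuildConfig) -> str:
    """Argmax of the removal score over the current taxa.

    Scores are computed on the non-trivial sub-family (the incompatibility
    graph ignores singletons).  Ties keep the smallest taxon in the natural
    label order (the default, which makes the greedy independent of the
    input order), or the earliest-encountered taxon under
    ``tie_break='first-encounter'``.
    """
    from .network import label_sort_key

    scored = cur.nontrivial_set()
    candidates = _removal_candidates(cur)
    if cfg.tie_break == "lexicographic":
        candidates = sorted(candidates, key=label_sort_key)
    best, best_s = None, None
    for t in candidates:
        s = score(scored, t, p, q, degree_method=cfg.degree_method)
        if best_s is None or s > best_s:
            best, best_s = t, s
    return best


def _removal_candidates(cur: ClusterSet) -> list[str]:
    """Taxa eligible for removal: those shared by some incompatible pair.

    Only a taxon lying in the intersection of two conflicting clusters can
    resolve their conflict without merely shrinking one of them away; an
    incompatible set always has at least one such taxon.  On {{1,2},{2,3}}
    the only candidate is taxon 2.
    """
    scored = cur.nontrivial_set()
    return [t for t in cur.taxa
            if taxon_incompatibility_degree(scored, t, method="shared") > 0]


def _removal_step(cur: ClusterSet, x: str) -> RemovalStep:
    removed = restrict_remove(cur, {x})
    collapsed, cmap = collapse_maximal_st_sets(removed)
    return RemovalStep(x, meta_base(x), cur, cmap, collapsed)


def frin_removal(y: ClusterSet, k: int, p: float, q: float,
                 cfg: BuildConfig) -> RemovalTrace | None:
    """Greedy removal: repeatedly delete the highest-scoring taxon (and
    re-collapse) until the remainder is compatible; at most ``k`` rounds.
    Returns ``None`` when ``k`` rounds do not reach compatibility."""
    cur = y
    steps: list[RemovalStep] = []
    while not is_compatible_set(cur):
        if len(steps) == k:
            return None
        x = _pick_removal(cur, p, q, cfg)
        if x is None:  # pragma: no cover - incompatible sets always have one
            return None
        st = _removal_step(cur, x)
        steps.append(st)
        cur = st.after
    return RemovalTrace(tuple(steps), (p, q))


def cass_removal(y: ClusterSet, k: int, cfg: BuildConfig):
    """Depth-first enumeration of all removal sequences of length <= ``k``
    whose remainder is compatible, branching over the conflict-involved
    taxa of the current set in first-encounter order — the source of the
    baseline's input-order dependence.  Lazily yields one trace per
    sequence."""

    def rec(cur: ClusterSet, steps: tuple[RemovalStep, ...]):
        if is_compatible_set(cur):
            yield RemovalTrace(steps, None)
            return
        if len(steps) == k:
            return
        for x in _removal_candidates(cur):
            st = _removal_step(cur, x)
            yield from rec(st.after, steps + (st,))

    yield from rec(y, ())


# -- reinsertion ---------------------------------------------------------


def _graft_subtree(net: PhyloNetwork, leaf: int, sub: ClusterSet) -> None:
    """Replace ``leaf`` in place by the tree of the compatible family ``sub``."""
    tree = tree_from_compatible_clusters(sub)
    mapping = {tree.root: leaf}
    net.set_label(leaf, None)
    for u, v in tree.dfs_edges():
        mapping[v] = net.new_node(label=tree.label(v))
        net.add_edge(mapping[u], mapping[v])


def _expand_network(net: PhyloNetwork, cmap: CollapseMap,
                    inner_from: ClusterSet | None = None) -> PhyloNetwork:
    """Expand collapsed meta-taxon leaves back into subtrees.

    Entries are unwound in reverse collapse order.  The subtree of a meta
    comes from the clusters it absorbed; with ``inner_from`` given (used at
    assembly time) the nested structure is taken from that full cluster set
    instead, so compatible clusters that sit inside an ST-set but outside
    the component are restored too.
    """
    net = net.copy()
    for entry in reversed(cmap.entries):
        target = next((v for v in net.leaves() if net.label(v) == entry.label),
                      None)
        if target is None:
            raise ValueError(f"meta-taxon {entry.label!r} is not a leaf")
        if inner_from is not None:
            base = meta_base(entry.label)
            members = [t for t in inner_from.taxa if t in base]
            inner = [tuple(sorted(c, key=inner_from.index))
                     for c in inner_from.clusters if c < base]
        else:
            members = list(entry.members)
            order = {t: i for i, t in enumerate(members)}
            inner = [tuple(sorted(c, key=order.__getitem__))
                     for c in entry.inner]
        sub = ClusterSet(inner, universe=members)
        _graft_subtree(net, target, sub)
    return net


def _edge_candidates(net: PhyloNetwork) -> tuple[PhyloNetwork, tuple[int, int], list]:
    """Copy the network, hang a synthetic root edge above the root, and list
    placement edges in depth-first discovery order (root edge first)."""
    work = net.copy()
    old_root = work.root
    syn = work.new_node()
    work.add_edge(syn, old_root)
    edges = [(syn, old_root)] + [e for e in work.dfs_edges()
                                 if e != (syn, old_root)]
    return work, (syn, old_root), edges


def _place(net: PhyloNetwork, syn_root: int, e1, e2, label: str) -> PhyloNetwork:
    """Subdivide the two chosen edges, join the subdivision points to a new
    reticulation whose single child is the reinserted leaf."""
    work = net.copy()
    s1 = work.subdivide(*e1)
    if e2 == e1:
        e2 = (s1, e1[1])
    s2 = work.subdivide(*e2)
    ret = work.new_node()
    work.add_edge(s1, ret)
    work.add_edge(s2, ret)
    work.add_edge(ret, work.new_node(label=label))
    # drop the synthetic root if nothing attached to its edge
    if work.g.has_node(syn_root) and work.g.out_degree(syn_root) == 1:
        work.remove_node(syn_root)
    return work


def _cleanup(net: PhyloNetwork) -> PhyloNetwork:
    """Drop unlabeled out-degree-1 roots and suppress degree-through nodes.

    A suppression that would create a parallel edge (both subdivision points
    of one original edge feeding the same reticulation) is skipped, since the
    digraph cannot carry multi-edges.
    """
    net = net.copy()
    changed = True
    while changed:
        changed = False
        root = net.root
        if net.g.out_degree(root) == 1 and net.label(root) is None:
            net.remove_node(root)
            changed = True
            continue
        for v in net.nodes():
            if (net.g.in_degree(v) == 1 and net.g.out_degree(v) == 1
                    and net.label(v) is None):
                (p,) = net.parents(v)
                (c,) = net.children(v)
                if not net.g.has_edge(p, c):
                    net.remove_node(v)
                    net.add_edge(p, c)
                    changed = True
                    break
    return net


def _reticulation_free_below_bridges(net: PhyloNetwork) -> bool:
    """Simple-network test used by the builder: no bridge may have a
    reticulation strictly below it (pendant pure subtrees are fine)."""
    import networkx as nx

    und = net.g.to_undirected()
    bridges = set(nx.bridges(und))
    rets = set(net.reticulations())
    if not rets:
        return True
    for u, v in net.edges():
        if (u, v) in bridges or (v, u) in bridges:
            below = nx.descendants(net.g, v) | {v}
            if below & rets:
                return False
    return True


def reinsert(t: PhyloNetwork, trace: RemovalTrace, y: ClusterSet,
             cfg: BuildConfig, require_simple: bool = True):
    """Re-add the removed taxa of ``trace`` to tree ``t`` in reverse removal
    order, lazily yielding every simple network that represents ``y``.

    For each removed item the per-step collapse is first expanded, then all
    ordered pairs of edges (including a synthetic edge above the root) are
    tried as the two reticulation attachment points; partial networks that
    fail to represent the corresponding intermediate cluster set are pruned.
    With ``require_simple=False`` the final no-reticulation-below-a-bridge
    check is skipped (used for merged groups of overlapping components,
    whose joint network is legitimately not simple).
    """
    steps = trace.steps

    def rec(net: PhyloNetwork, i: int):
        if i < 0:
            net = _cleanup(net)
            if not require_simple or _reticulation_free_below_bridges(net):
                yield net
            return
        st = steps[i]
        base = _cleanup(_expand_network(net, st.collapse))
        work, root_edge, edges = _edge_candidates(base)
        for e1, e2 in itertools.product(edges, repeat=2):
            cand = _place(work, root_edge[0], e1, e2, st.removed)
            try:
                ok = represents(cand, st.before, cap=cfg.reticulation_cap)
            except ResourceError:
                return
            if ok:
                yield from rec(cand, i - 1)

    yield from rec(t, len(steps) - 1)


# -- backbone and assembly ----------------------------------------------


def backbone_tree(y: ClusterSet, components: list[ClusterSet]) -> PhyloNetwork:
    """Tree scaffold for the full network: the clusters outside every
    component, each component's taxon set, and each maximal subset of it not
    separated by the component's clusters (grouped by membership pattern)."""
    in_comp = set()
    for comp in components:
        in_comp.update(comp.clusters)
    orders = [o for o in y.cluster_orders if frozenset(o) not in in_comp]
    for comp in components:
        xi = [t for t in y.taxa if t in comp.universe]
        orders.append(tuple(xi))
        classes: dict[tuple, list] = {}
        for t in xi:
            sig = tuple(t in c for c in comp.clusters)
            classes.setdefault(sig, []).append(t)
        for members in classes.values():
            if len(members) >= 2:
                orders.append(tuple(members))
    scaffold = ClusterSet(orders, universe=y.taxa)
    try:
        return tree_from_compatible_clusters(scaffold)
    except ValueError as exc:  # pragma: no cover - violates the step-3 contract
        raise ResourceError(f"backbone cluster set is incompatible: {exc}")


def assemble(backbone: PhyloNetwork, simple_nets: list[PhyloNetwork],
             components: list[ClusterSet], y: ClusterSet) -> PhyloNetwork:
    """Graft each component's simple network into the backbone at the node
    whose cluster is the component's taxon set, then expand meta-taxon
    leaves into subtrees using the full input cluster set."""
    if len(simple_nets) != len(components):
        raise ValueError("one simple network per component is required")
    net = backbone.copy()
    for comp, simple in zip(components, simple_nets):
        xi = frozenset(comp.universe)
        target = next((v for v in net.nodes()
                       if net.descendant_leaves(v) == xi), None)
        if target is None:  # pragma: no cover
            raise ValueError(f"backbone has no node for component {sorted(xi)}")
        import networkx as nx

        doomed = nx.descendants(net.g, target) | {target}
        parents = net.parents(target)
        net.g.remove_nodes_from(doomed)
        mapping: dict[int, int] = {}
        for v in simple.nodes():
            mapping[v] = net.new_node(label=simple.label(v))
        for u, v in simple.edges():
            net.add_edge(mapping[u], mapping[v])
        for p in parents:
            net.add_edge(p, mapping[simple.root])
    # expand meta-taxon leaves against the full cluster set
    changed = True
    while changed:
        changed = False
        for v in net.leaves():
            lab = net.label(v)
            if lab and lab.startswith(META_PREFIX):
                base = meta_base(lab)
                members = [t for t in y.taxa if t in base]
                inner = [tuple(sorted(c, key=y.index))
                         for c in y.clusters if c < base]
                _graft_subtree(net, v, ClusterSet(inner, universe=members))
                changed = True
                break
    net.validate()
    return net


# -- top-level search ----------------------------------------------------


def _component_candidates(comp: ClusterSet, cfg: BuildConfig,
                          require_simple: bool = True):
    """Simple-network candidates for one incompatibility component.

    Frin mode sweeps the (p, q) weightings at increasing level bounds and
    keeps one network per distinct trace; Cass mode stops at the first
    network its depth-first enumeration finds, which is what ties its
    output to the input order.
    """
    collapsed, _m0 = collapse_maximal_st_sets(comp)
    for k in range(cfg.max_k + 1):
        _log.info("component on %d taxa: trying level k=%d (%s mode)",
                  len(comp.universe), k, cfg.mode)
        found = []
        if cfg.mode == "frin":
            seen: set[tuple] = set()
            traces = []
            for p, q in weight_pairs(cfg.weight_step):
                tr = frin_removal(collapsed, k, p, q, cfg)
                _log.debug("(p,q)=(%.1f,%.1f): trace %s", p, q,
                           None if tr is None else
                           [s.removed for s in tr.steps])
                if tr is not None and tr.key() not in seen:
                    seen.add(tr.key())
                    traces.append(tr)
            for tr in traces:
                tree = tree_from_compatible_clusters(tr.final(collapsed))
                gen = reinsert(tree, tr, collapsed, cfg, require_simple)
                if cfg.keep_placements == "all":
                    picked = list(itertools.islice(gen, cfg.placement_cap))
                else:
                    first = next(gen, None)
                    picked = [] if first is None else [first]
                seen_nets: set[str] = set()
                for net in picked:
                    form = canonical_form(net)
                    if form not in seen_nets:
                        seen_nets.add(form)
                        found.append((net, tr, k))
        elif cfg.mode == "cass":
            for tr in cass_removal(collapsed, k, cfg):
                tree = tree_from_compatible_clusters(tr.final(collapsed))
                net = next(reinsert(tree, tr, collapsed, cfg, require_simple), None)
                if net is not None:
                    found.append((net, tr, k))
                    break
        else:
            raise ValueError(f"unknown mode: {cfg.mode!r}")
        if found:
            return found
    raise ResourceError(
        f"no simple level-<={cfg.max_k} network found for a component on "
        f"{len(comp.universe)} taxa; raise max_k")


def _merge_overlapping(y: ClusterSet, comps: list[ClusterSet]) -> list[ClusterSet]:
    """Union incompatibility components whose taxon sets overlap or nest.

    The backbone/assembly step substitutes one subnetwork per component at
    the node carrying its taxon set, which is only well defined when those
    taxon sets are pairwise disjoint; overlapping components are therefore
    built together as one group.
    """
    groups = [set(c.universe) for c in comps]
    members = [[i] for i in range(len(comps))]
    changed = True
    while changed:
        changed = False
        for i in range(len(groups)):
            for j in range(i + 1, len(groups)):
                if groups[i] & groups[j]:
                    groups[i] |= groups.pop(j)
                    members[i] += members.pop(j)
                    changed = True
                    break
            if changed:
                break
    out = []
    for idx in members:
        if len(idx) == 1:
            out.append(comps[idx[0]])
            continue
        clusters = set().union(*(set(comps[i].clusters) for i in idx))
        uni = frozenset().union(*(comps[i].universe for i in idx))
        # compatible clusters nested inside the group's taxa would otherwise
        # be discarded with the backbone subtree the group replaces
        orders = [o for o in y.cluster_orders
                  if frozenset(o) in clusters
                  or (len(o) >= 2 and frozenset(o) < uni)]
        out.append(y.replace_clusters(orders, universe=[t for t in y.taxa
                                                        if t in uni]))
    out.sort(key=lambda cs: min(y.index(t) for t in cs.universe))
    return out


def build_candidates(y: ClusterSet, cfg: BuildConfig | None = None) -> list[Candidate]:
    """All distinct full-network candidates, sorted by (r, c, canonical form)."""
    cfg = cfg or BuildConfig()
    if len(y.universe) == 0:
        raise ValueError("empty cluster set")
    raw = incompatibility_components(y)
    comps = _merge_overlapping(y, raw)
    if not comps:
        tree = tree_from_compatible_clusters(y)
        return [Candidate(tree, 0, 0, 0, 0, (), canonical_form(tree))]
    merged = len(raw) > len(comps)
    per_comp = [_component_candidates(comp, cfg, require_simple=not merged
                                      or any(comp == c for c in raw))
                for comp in comps]
    n_combo = 1
    for lst in per_comp:
        n_combo *= len(lst)
    combos = itertools.product(*per_comp)
    if n_combo > cfg.max_combinations:
        # keep the per-component front-runners only
        combos = zip(*[[min(lst, key=lambda it: len(it[1]))] for lst in per_comp])
    out: dict[str, Candidate] = {}
    for combo in combos:
        nets = [it[0] for it in combo]
        traces = tuple(it[1] for it in combo)
        k_used = max(it[2] for it in combo)
        full = assemble(backbone_tree(y, comps), nets, comps, y)
        if not represents(full, y, cap=cfg.reticulation_cap):
            continue
        form = canonical_form(full)
        if form in out:
            continue
        out[form] = Candidate(
            network=full,
            k=k_used,
            r=reticulation_number(full),
            c=redundant_cluster_count(full, y, cap=cfg.reticulation_cap),
            level=level(full),
            traces=traces,
            form=form,
        )
    if not out:
        raise ResourceError("no assembled candidate represents the input")
    return sorted(out.values(), key=lambda c: (c.r, c.c, c.form))


def build(y: ClusterSet, cfg: BuildConfig | None = None) -> Candidate:
    """Construct the final network: the candidate with the fewest
    reticulations, then the fewest redundant clusters (canonical-form tie
    break makes the result a pure function of the input order)."""
    return build_candidates(y, cfg)[0]
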