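"""Cluster compatibility, incompatibility statistics, ST-sets, collapsing."""

import itertools
import random

import pytest

from frinet import (
    ClusterSet,
    collapse_maximal_st_sets,
    expand,
    incompatibility_components,
    incompatibility_degree,
    incompatibility_graph,
    is_compatible_pair,
    is_compatible_set,
    is_st_set,
    restrict_remove,
    restrict_to,
    taxon_frequency,
    taxon_incompatibility_degree,
)
from frinet.fixtures import FixtureSpec, make_fixture, random_laminar_family, union_clusters


@pytest.mark.parametrize("c1,c2,expected", [
    ({"1", "2"}, {"2", "3"}, False),   # overlapping, neither nested
    ({"1", "2"}, {"1", "2"}, True),    # equal
    ({"1", "2"}, {"3", "4"}, True),    # disjoint
    ({"1", "2"}, {"1", "2", "3"}, True),  # nested
])
def test_pairwise_compatibility(c1, c2, expected):
    assert is_compatible_pair(c1, c2) is expected
    assert is_compatible_pair(c2, c1) is expected


def test_set_compatibility(micro):
    assert not is_compatible_set(micro)
    assert is_compatible_set(ClusterSet([("1", "2"), ("1", "2", "3")]))


def test_laminar_families_are_compatible(rng):
    for _ in range(25):
        fam = random_laminar_family(rng.randint(4, 12), rng)
        assert is_compatible_set(fam)


def test_incompatibility_graph_micro(micro):
    g = incompatibility_graph(micro)
    assert g.number_of_nodes() == 2
    assert g.number_of_edges() == 1
    assert len(incompatibility_components(micro)) == 1


def test_incompatibility_graph_matches_pair_scan(ex5):
    """Edge count equals an independent all-pairs compatibility scan."""
    nontrivial = [c for c in ex5.clusters if len(c) >= 2]
    expected = sum(
        1 for a, b in itertools.combinations(nontrivial, 2)
        if not (a.isdisjoint(b) or a <= b or b <= a))
    assert incompatibility_degree(ex5) == expected == 18


def test_compatible_set_has_degree_zero():
    assert incompatibility_degree(ClusterSet([("1", "2"), ("3", "4")])) == 0


def test_taxon_frequency_worked_example(micro):
    assert [taxon_frequency(micro, t) for t in "123"] == [1, 2, 1]
    with pytest.raises(ValueError):
        taxon_frequency(micro, "9")


def test_taxon_frequency_membership_scan(ex5):
    for t in ex5.taxa:
        assert taxon_frequency(ex5, t) == sum(1 for c in ex5.clusters if t in c)


def test_frequency_sum_equals_cluster_size_sum(ex5, ex10):
    for y in (ex5, ex10):
        assert sum(len(c) for c in y.clusters) == \
            sum(taxon_frequency(y, t) for t in y.taxa)


def test_taxon_incompatibility_degree_worked_example(micro):
    """The printed per-taxon conflict degrees on {{1,2},{2,3}}: only taxon 2,
    shared by the conflicting pair, carries the conflict."""
    assert [taxon_incompatibility_degree(micro, t) for t in "123"] == [0, 1, 0]


def test_taxon_incompatibility_degree_removal_semantics(micro):
    got = [taxon_incompatibility_degree(micro, t, method="removal")
           for t in "123"]
    assert got == [1, 1, 1]  # node deaths also remove edges under this reading
    d = incompatibility_degree(micro)
    for t, v in zip("123", got):
        assert v == d - incompatibility_degree(restrict_remove(micro, {t}))


def test_degree_nonnegative_and_zero_when_compatible(ex5):
    compat = ClusterSet([("1", "2"), ("1", "2", "3"), ("4", "5")])
    for t in compat.taxa:
        for method in ("shared", "removal"):
            assert taxon_incompatibility_degree(compat, t, method) == 0
    for t in ex5.taxa:
        assert taxon_incompatibility_degree(ex5, t, "removal") >= 0


def test_restrict_remove(micro, ex10):
    got = restrict_remove(micro, {"2"})
    assert set(got.clusters) == {frozenset("1"), frozenset("3")}
    assert got.universe == {"1", "3"}
    assert restrict_remove(micro, set()) == micro
    # per-cluster set-difference oracle
    removed = restrict_remove(ex10, {"7", "8"})
    expected = {frozenset(c - {"7", "8"}) for c in ex10.clusters} - {frozenset()}
    assert set(removed.clusters) == expected


def test_restriction_never_increases_degree(ex5, ex10, rng):
    for y in (ex5, ex10):
        base = incompatibility_degree(y)
        for _ in range(10):
            s = set(rng.sample(list(y.universe), rng.randint(1, 3)))
            assert incompatibility_degree(restrict_remove(y, s)) <= base


def test_is_st_set_basics():
    y = ClusterSet([("1", "2"), ("1", "2", "3"), ("3", "4")])
    assert is_st_set(y, {"1", "2"})
    y2 = ClusterSet([("1", "2"), ("2", "3")])
    assert not is_st_set(y2, {"1", "2"})
    with pytest.raises(ValueError):
        is_st_set(y, {"1"})


def _st_set_oracle(y, s):
    """Definition-level check, independent of the library's restriction code."""
    s = frozenset(s)
    for c in y.clusters:
        if not (s.isdisjoint(c) or s <= c or c <= s):
            return False
    restricted = [c & s for c in y.clusters if c & s]
    return all(a.isdisjoint(b) or a <= b or b <= a
               for a, b in itertools.combinations(
                   [c for c in set(restricted) if len(c) >= 2], 2))


def test_is_st_set_matches_oracle_on_all_pairs(ex5, ex10):
    for y in (ex5, ex10):
        for s in itertools.combinations(y.universe, 2):
            assert is_st_set(y, s) == _st_set_oracle(y, s), s


def test_collapse_finds_maximal_st_sets(ex10):
    from frinet.clusters import meta_base

    comp = incompatibility_components(ex10)[0]
    collapsed, cmap = collapse_maximal_st_sets(comp)
    bases = {meta_base(t) for t in collapsed.taxa if t.startswith("&")}
    assert bases == {frozenset({"2", "3", "4"}), frozenset({"5", "6"}),
                     frozenset({"7", "8"})}
    # result has no ST-set of size >= 2
    for s in itertools.combinations(collapsed.universe, 2):
        assert not is_st_set(collapsed, s)


def test_collapse_leaves_micro_unchanged(micro):
    collapsed, cmap = collapse_maximal_st_sets(micro)
    assert collapsed == micro
    assert not cmap.entries
    # oracle: no 2- or 3-subset of the universe qualifies as an ST-set
    for k in (2, 3):
        for s in itertools.combinations(micro.universe, k):
            assert not _st_set_oracle(micro, s)


def test_collapse_is_idempotent(ex10):
    comp = incompatibility_components(ex10)[0]
    once, _ = collapse_maximal_st_sets(comp)
    twice, cmap2 = collapse_maximal_st_sets(once)
    assert twice == once
    assert not cmap2.entries


def test_collapse_expand_round_trip(ex10, rng):
    families = [incompatibility_components(ex10)[0]]
    for seed in range(10):
        y = union_clusters(make_fixture(FixtureSpec(taxa=8, seed=seed)))
        families.append(y)
    for y in families:
        collapsed, cmap = collapse_maximal_st_sets(y)
        assert expand(collapsed, cmap) == y


def test_nested_collapse_round_trip():
    # {1,3} collapses first, then merges with 2 into one maximal ST-set
    y = ClusterSet([("1", "3"), ("1", "2", "3"), ("4", "5"), ("4", "6"),
                    ("5", "6"), ("1", "2", "3", "4")])
    collapsed, cmap = collapse_maximal_st_sets(y)
    assert len(cmap.entries) >= 2
    assert expand(collapsed, cmap) == y


def test_restrict_to_intersects():
    y = ClusterSet([("1", "2", "3"), ("3", "4"), ("5",)])
    got = restrict_to(y, {"3", "4"})
    assert set(got.clusters) == {frozenset({"3"}), frozenset({"3", "4"})}
    assert got.universe == {"3", "4"}


try:
    from hypothesis import given, settings, strategies as st

    taxa_pool = [str(i) for i in range(1, 7)]
    cluster_families = st.lists(
        st.sets(st.sampled_from(taxa_pool), min_size=1, max_size=5).map(
            lambda s: tuple(sorted(s))),
        min_size=1, max_size=8)

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(cluster_families)
    def test_collapse_expand_identity_property(orders):
        """expand ∘ collapse is the identity on arbitrary cluster families."""
        y = ClusterSet(orders)
        collapsed, cmap = collapse_maximal_st_sets(y)
        assert expand(collapsed, cmap) == y
        again, cmap2 = collapse_maximal_st_sets(collapsed)
        assert again == collapsed and not cmap2.entries

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(cluster_families, st.sampled_from(taxa_pool))
    def test_removal_degree_monotone_property(orders, x):
        """Deleting a taxon never increases the incompatibility degree."""
        y = ClusterSet(orders)
        if x not in y.universe:
            return
        assert incompatibility_degree(restrict_remove(y, {x})) <= \
            incompatibility_degree(y)
except ImportError:  # pragma: no cover - hypothesis is an optional test dep
    pass
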