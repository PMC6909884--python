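"""The construction core: scoring, removal, reinsertion, assembly, build."""

import pytest

from frinet import (
    BuildConfig,
    ClusterSet,
    build,
    build_candidates,
    canonical_form,
    cass_removal,
    clusters_from_tree,
    collapse_maximal_st_sets,
    frin_removal,
    incompatibility_components,
    level,
    represents,
    reticulation_number,
    score,
    tree_from_compatible_clusters,
    weight_pairs,
)
from frinet.builder import backbone_tree, reinsert
from frinet.fixtures import FixtureSpec, make_fixture, union_clusters


def test_weight_pairs_step_point_one():
    pairs = weight_pairs(0.1)
    assert len(pairs) == 10
    assert pairs[0] == (0.1, 0.9)
    assert pairs[-1] == (1.0, 0.0)
    assert all(abs(p + q - 1) < 1e-9 for p, q in pairs)
    assert all(0 < p <= 1 and 0 <= q < 1 for p, q in pairs)


def test_weight_pairs_step_half_and_errors():
    assert weight_pairs(0.5) == [(0.5, 0.5), (1.0, 0.0)]
    with pytest.raises(ValueError):
        weight_pairs(0.3)


def test_score_worked_example(micro):
    assert score(micro, "2", 0.5, 0.5) == pytest.approx(1.5)
    assert score(micro, "2", 1.0, 0.0) == pytest.approx(2.0)  # reduces to f
    assert score(micro, "1", 0.5, 0.5) == pytest.approx(0.5)


def test_score_argmax_matches_brute_force(ex5):
    comp = incompatibility_components(ex5)[0]
    best = max(comp.taxa, key=lambda t: score(comp, t, 0.5, 0.5))
    assert best == "4"  # highest frequency and conflict involvement


def test_frin_removal_micro(micro):
    cfg = BuildConfig()
    for p, q in weight_pairs():
        if q == 0:
            continue
        tr = frin_removal(micro, 1, p, q, cfg)
        assert tr is not None
        assert [s.removed for s in tr.steps] == ["2"]
    compat = ClusterSet([("1", "2"), ("1", "2", "3")])
    assert len(frin_removal(compat, 3, 0.5, 0.5, cfg).steps) == 0


def test_frin_removal_respects_budget(micro):
    assert frin_removal(micro, 0, 0.5, 0.5, BuildConfig()) is None


def test_frin_removal_remainder_compatible(ex5):
    from frinet import is_compatible_set

    comp = incompatibility_components(ex5)[0]
    collapsed, _ = collapse_maximal_st_sets(comp)
    tr = frin_removal(collapsed, 3, 0.5, 0.5, BuildConfig())
    assert tr is not None and len(tr.steps) <= 3
    assert is_compatible_set(tr.final(collapsed))


def test_cass_removal_micro(micro):
    cfg = BuildConfig(mode="cass")
    assert list(cass_removal(micro, 0, cfg)) == []
    traces = list(cass_removal(micro, 1, cfg))
    assert len(traces) == 1
    assert [s.removed for s in traces[0].steps] == ["2"]


def test_cass_removal_remainders_compatible(ex10):
    from frinet import is_compatible_set

    comp = incompatibility_components(ex10)[0]
    collapsed, _ = collapse_maximal_st_sets(comp)
    traces = list(cass_removal(collapsed, 3, BuildConfig(mode="cass")))
    assert traces
    for tr in traces:
        assert is_compatible_set(tr.final(collapsed))
    # a superset of frin's traces at the same budget
    frin_keys = set()
    for p, q in weight_pairs():
        tr = frin_removal(collapsed, 3, p, q, BuildConfig())
        if tr:
            frin_keys.add(tr.key())
    assert frin_keys <= {tr.key() for tr in traces}


def test_reinsert_micro(micro):
    cfg = BuildConfig()
    tr = frin_removal(micro, 1, 0.5, 0.5, cfg)
    tree = tree_from_compatible_clusters(tr.final(micro))
    nets = list(reinsert(tree, tr, micro, cfg))
    assert nets
    for net in nets:
        assert represents(net, micro)
        assert reticulation_number(net) == 1


def test_reinsert_empty_trace_returns_tree(micro):
    compat = ClusterSet([("1", "2"), ("1", "2", "3")])
    cfg = BuildConfig()
    tr = frin_removal(compat, 2, 0.5, 0.5, cfg)
    tree = tree_from_compatible_clusters(compat)
    (only,) = list(reinsert(tree, tr, compat, cfg))
    assert reticulation_number(only) == 0


def test_backbone_cases(ex5):
    # no incompatibility: backbone is the tree of the set itself
    compat = ClusterSet([("1", "2"), ("3", "4")], universe=list("12345"))
    bb = backbone_tree(compat, [])
    assert set(clusters_from_tree(bb).nontrivial) == set(compat.nontrivial)
    # one component spanning all taxa: star around the component node
    comps = incompatibility_components(ex5)
    bb5 = backbone_tree(ex5, comps)
    assert bb5.leaf_labels() == ex5.universe


def test_build_compatible_set_is_exact_tree():
    y = ClusterSet([("1", "2"), ("1", "2", "3"), ("4", "5")],
                   universe=list("123456"))
    cand = build(y, BuildConfig())
    assert (cand.r, cand.c, cand.level) == (0, 0, 0)
    assert set(clusters_from_tree(cand.network).nontrivial) == set(y.nontrivial)


def test_build_single_tree_input_returns_that_tree():
    for seed in range(5):
        (tree,) = make_fixture(FixtureSpec(taxa=8, trees=1, seed=seed))
        y = clusters_from_tree(tree)
        cand = build(y, BuildConfig())
        assert cand.r == 0 and cand.c == 0
        assert canonical_form(cand.network) == canonical_form(tree)


@pytest.mark.parametrize("mode", ["frin", "cass"])
def test_build_represents_fixtures(mode):
    for seed in range(15):
        y = union_clusters(make_fixture(FixtureSpec(taxa=8, seed=seed)))
        cand = build(y, BuildConfig(mode=mode))
        assert represents(cand.network, y)
        assert cand.r == reticulation_number(cand.network)
        assert cand.level == level(cand.network)


def test_selected_candidate_is_pareto_undominated(ex5):
    pool = build_candidates(ex5, BuildConfig(keep_placements="all"))
    best = pool[0]
    assert not any((c.r, c.c) < (best.r, best.c) or
                   (c.r < best.r and c.c <= best.c) for c in pool[1:])


def test_output_leaves_are_input_taxa(ex10):
    cand = build(ex10, BuildConfig())
    assert cand.network.leaf_labels() == ex10.universe
    assert not any(lab.startswith("&") for lab in cand.network.leaf_labels())


def test_nested_conflicts_are_merged_and_built():
    """Components with overlapping taxon sets are constructed jointly."""
    y = union_clusters(make_fixture(FixtureSpec(taxa=8, trees=2, moves=2, seed=0)))
    comps = incompatibility_components(y)
    unions = [set(c.universe) for c in comps]
    assert any(a & b for i, a in enumerate(unions) for b in unions[i + 1:])
    cand = build(y, BuildConfig())
    assert represents(cand.network, y)


def test_build_mode_validation(micro):
    with pytest.raises(ValueError):
        build(micro, BuildConfig(mode="bogus"))
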