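"""Rooted-tree core: Newick I/O, rooting, clades, triples, consensus, RF."""

import itertools

import numpy as np
import pytest

from redphylo.trees import (
    NewickError,
    TreeError,
    canonical_newick,
    extract_rooted_triples,
    is_monophyletic,
    majority_rule_consensus,
    parse_newick,
    prune_to,
    rf_distance,
    root_with_outgroup,
    unrooted_rf_distance,
    write_newick,
)

from conftest import leaf_names, random_rooted_tree


class TestNewick:
    def test_minimal_rooted_tree(self):
        t = parse_newick("((A,B),C);")
        assert sorted(t.leaf_labels()) == ["A", "B", "C"]
        assert len(t.root.children) == 2
        assert is_monophyletic(t, {"A", "B"})

    def test_branch_lengths_attached(self):
        t = parse_newick("((A:1,B:1):0.5,C:1.5);")
        inner = t.root.children[0]
        assert inner.length == 0.5
        assert [c.length for c in inner.children] == [1.0, 1.0]
        assert t.root.children[1].length == 1.5

    def test_numeric_internal_labels_read_as_supports(self):
        t = parse_newick("((A,B)95:0.5,C);")
        assert t.root.children[0].support == 95.0
        t2 = parse_newick("((A,B)95:0.5,C);", support_labels=False)
        assert t2.root.children[0].label == "95"

    @pytest.mark.parametrize(
        "bad", ["", "((A,B),C", "(A,B));", "((A,),B);", "(A,B);x", "((A,B)C"]
    )
    def test_malformed_newick_raises_with_offset(self, bad):
        with pytest.raises(NewickError) as exc:
            parse_newick(bad)
        assert exc.value.offset >= 0

    def test_round_trip_random_trees_lossless(self, rng):
        """parse(write(t)) preserves topology, labels and lengths."""
        for _ in range(100):
            t = random_rooted_tree(rng, leaf_names(15), with_lengths=True)
            back = parse_newick(write_newick(t))
            assert rf_distance(t, back) == 0
            orig = {
                frozenset([n.label]): n.length
                for n in t.postorder()
                if n.is_leaf
            }
            rest = {
                frozenset([n.label]): n.length
                for n in back.postorder()
                if n.is_leaf
            }
            for k in orig:
                assert rest[k] == pytest.approx(orig[k], rel=1e-10)

    def test_duplicate_leaf_labels_rejected(self):
        with pytest.raises(TreeError, match="duplicate"):
            parse_newick("((A,A),B);")


class TestRooting:
    def test_root_on_outgroup_edge(self):
        t = parse_newick("((A,B),(C,Out));")
        r = root_with_outgroup(t, {"Out"})
        sets = r._node_leafsets()
        assert {sets[c] for c in r.root.children} == {
            frozenset({"Out"}),
            frozenset({"A", "B", "C"}),
        }

    def test_already_rooted_tree_unchanged(self):
        t = parse_newick("(((A,B),C),Out);")
        r = root_with_outgroup(t, {"Out"})
        assert canonical_newick(r) == canonical_newick(t)

    def test_random_reroot_preserves_unrooted_topology(self, rng):
        """Re-rooting never alters the unrooted topology (RF oracle = 0)."""
        for _ in range(10):
            t = random_rooted_tree(rng, leaf_names(10))
            out = leaf_names(10)[rng.integers(10)]
            r = root_with_outgroup(t, {out})
            assert unrooted_rf_distance(t, r) == 0
            sets = r._node_leafsets()
            assert frozenset({out}) in {sets[c] for c in r.root.children}

    def test_inseparable_outgroup_reports_conflict(self):
        t = parse_newick("((A,B),(C,D));")
        with pytest.raises(TreeError, match="separable"):
            root_with_outgroup(t, {"A", "C"})

    def test_reroot_agrees_with_dendropy(self, rng):
        dendropy = pytest.importorskip("dendropy")
        for seed in range(5):
            local = np.random.default_rng(seed)
            t = random_rooted_tree(local, leaf_names(8), with_lengths=True)
            out = leaf_names(8)[local.integers(8)]
            mine = root_with_outgroup(t, {out})
            tns = dendropy.TaxonNamespace()
            dt = dendropy.Tree.get(
                data=write_newick(t), schema="newick", taxon_namespace=tns
            )
            node = dt.find_node_with_taxon_label(out)
            dt.to_outgroup_position(node, update_bipartitions=True)
            dmine = dendropy.Tree.get(
                data=write_newick(mine), schema="newick", taxon_namespace=tns
            )
            dt.encode_bipartitions()
            dmine.encode_bipartitions()
            rf = dendropy.calculate.treecompare.symmetric_difference(dt, dmine)
            assert rf == 0


def _under(leaf, ancestor):
    node = leaf
    while node is not None:
        if node is ancestor:
            return True
        node = node.parent
    return False


class TestMonophyly:
    @pytest.mark.parametrize(
        "labels,expected", [({"A", "B"}, True), ({"A", "C"}, False)]
    )
    def test_examples(self, labels, expected):
        assert is_monophyletic(parse_newick("((A,B),C);"), labels) is expected

    def test_unknown_label_raises(self):
        with pytest.raises(TreeError, match="unknown"):
            is_monophyletic(parse_newick("((A,B),C);"), {"A", "Z"})

    def test_exhaustive_against_clade_enumeration(self, rng):
        """Every subset's verdict equals brute-force clade enumeration."""
        t = random_rooted_tree(rng, leaf_names(8))
        clades = {frozenset([l]) for l in leaf_names(8)}
        clades.update(t.clades(include_trivial=True))
        for r in range(1, 8):
            for combo in itertools.combinations(leaf_names(8), r):
                assert is_monophyletic(t, set(combo)) == (
                    frozenset(combo) in clades
                )


class TestRootedTriples:
    def test_three_leaf_resolution(self):
        (tri,) = extract_rooted_triples(parse_newick("((A,B),C);"))
        assert tri.cherry == frozenset({"A", "B"})
        assert tri.outlier == "C"

    def test_triple_count_is_n_choose_3(self, rng):
        t = random_rooted_tree(rng, leaf_names(5))
        assert len(extract_rooted_triples(t)) == 10

    def test_resolutions_match_pruned_subtrees(self, rng):
        """Prune-and-compare oracle on random 8-leaf trees."""
        for _ in range(5):
            t = random_rooted_tree(rng, leaf_names(8))
            for tri in extract_rooted_triples(t):
                sub = prune_to(t, set(tri.taxa))
                sets = sub._node_leafsets()
                cherries = [
                    sets[n]
                    for n in sub.postorder()
                    if not n.is_leaf and len(sets[n]) == 2
                ]
                assert cherries == [tri.cherry]

    def test_too_few_leaves_raises(self):
        with pytest.raises(TreeError):
            extract_rooted_triples(parse_newick("(A,B);"))


class TestConsensus:
    def test_identical_trees_full_support(self, rng):
        t = random_rooted_tree(rng, leaf_names(6))
        cons = majority_rule_consensus([t.copy() for _ in range(10)])
        assert rf_distance(cons, t) == 0
        supports = [
            n.support
            for n in cons.postorder()
            if not n.is_leaf and n.parent is not None
        ]
        assert supports and all(s == 100.0 for s in supports)

    def test_two_thirds_support_value(self):
        trees = [parse_newick("((A,B),C,D);")] * 2 + [parse_newick("((A,C),B,D);")]
        cons = majority_rule_consensus(trees, mode="strict")
        sets = cons._node_leafsets()
        (ab_node,) = [
            n for n in cons.postorder() if sets[n] == frozenset({"A", "B"})
        ]
        assert round(ab_node.support, 1) == 66.7

    def test_strict_mode_matches_bruteforce_tally(self, rng):
        """Strict consensus clades are exactly those counted >50%."""
        for _ in range(5):
            trees = [random_rooted_tree(rng, leaf_names(7)) for _ in range(9)]
            cons = majority_rule_consensus(trees, mode="strict")
            tally = {}
            for t in trees:
                for clade in set(t.clades()):
                    tally[clade] = tally.get(clade, 0) + 1
            majority = {c for c, k in tally.items() if k * 2 > len(trees)}
            assert set(cons.clades()) == majority
            for n in cons.postorder():
                if not n.is_leaf and n.parent is not None:
                    assert n.support > 50.0

    def test_extended_adds_compatible_minority_clades(self, rng):
        for _ in range(5):
            trees = [random_rooted_tree(rng, leaf_names(7)) for _ in range(9)]
            strict = set(majority_rule_consensus(trees, mode="strict").clades())
            extended = set(majority_rule_consensus(trees, mode="extended").clades())
            assert strict <= extended
            for a in extended:
                for b in extended:
                    assert a <= b or b <= a or not (a & b)

    def test_leaf_set_mismatch_lists_difference(self):
        with pytest.raises(TreeError, match="D"):
            majority_rule_consensus(
                [parse_newick("((A,B),C);"), parse_newick("((A,B),D);")]
            )

    def test_supports_in_range(self, rng):
        trees = [random_rooted_tree(rng, leaf_names(6)) for _ in range(7)]
        cons = majority_rule_consensus(trees)
        for n in cons.postorder():
            if n.support is not None:
                assert 0.0 <= n.support <= 100.0


class TestRFDistance:
    def test_identical_trees_zero(self, rng):
        t = random_rooted_tree(rng, leaf_names(9))
        assert rf_distance(t, t.copy()) == 0

    def test_clade_symmetric_difference(self):
        t1 = parse_newick("((A,B),(C,D));")
        t2 = parse_newick("((A,C),(B,D));")
        assert rf_distance(t1, t2) == 4  # clades {AB},{CD} vs {AC},{BD}
        assert unrooted_rf_distance(t1, t2) == 2

    def test_triangle_inequality(self, rng):
        for _ in range(10):
            a, b, c = (random_rooted_tree(rng, leaf_names(8)) for _ in range(3))
            assert rf_distance(a, c) <= rf_distance(a, b) + rf_distance(b, c)

    def test_leaf_set_mismatch_raises(self):
        with pytest.raises(TreeError):
            rf_distance(parse_newick("((A,B),C);"), parse_newick("((A,B),D);"))
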