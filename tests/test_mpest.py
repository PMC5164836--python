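"""Pseudo-likelihood species-tree estimation: counts, model, optimisation, search."""

import itertools
import math

import numpy as np
import pytest

from redphylo.mpest import (
    MPEST,
    TripleCountTable,
    count_triples,
    invert_concordance,
    optimize_branch_lengths,
    pseudo_log_likelihood,
    search_species_tree,
    triple_probabilities,
)
from redphylo.trees import (
    Node,
    RootedTree,
    TreeError,
    canonical_newick,
    extract_rooted_triples,
    parse_newick,
    rf_distance,
)

from conftest import leaf_names, random_rooted_tree


class TestCountTriples:
    def test_identical_gene_trees(self):
        trees = [parse_newick("((A,B),C);") for _ in range(10)]
        table = count_triples(trees)
        assert table.get_counts(("A", "B", "C")) == {"A": 0, "B": 0, "C": 10.0}

    def test_missing_taxa_shrink_totals(self):
        trees = [parse_newick("((A,B),C);"), parse_newick("(((A,B),C),D);")]
        table = count_triples(trees)
        assert sum(table.get_counts(("A", "B", "C")).values()) == 2
        assert sum(table.get_counts(("A", "B", "D")).values()) == 1

    def test_duplicate_species_label_raises(self):
        root = Node()
        x = Node()
        root.add_child(x)
        x.add_child(Node(label="A"))
        x.add_child(Node(label="B"))
        root.add_child(Node(label="C"))
        tree = RootedTree(root)
        tree.leaves()[0].label = "C"  # force duplicate post-validation
        with pytest.raises(TreeError, match="duplicate"):
            count_triples([tree])

    def test_counts_match_bruteforce_triple_extraction(self, rng):
        """Independent oracle: tally RootedTriples tree by tree."""
        trees = [random_rooted_tree(rng, leaf_names(8)) for _ in range(20)]
        table = count_triples(trees)
        expected: dict = {}
        for t in trees:
            for tri in extract_rooted_triples(t):
                expected.setdefault(tri.taxa, {l: 0 for l in tri.taxa})
                expected[tri.taxa][tri.outlier] += 1
        for taxa, cnt in expected.items():
            assert table.get_counts(taxa) == pytest.approx(cnt)


class TestTripleProbabilities:
    def test_star_tree_equiprobable(self):
        assert triple_probabilities(0.0) == pytest.approx((1 / 3, 1 / 3, 1 / 3))

    def test_deep_coalescence_vanishes_for_long_branches(self):
        p = triple_probabilities(50.0)
        assert p[0] == pytest.approx(1.0) and p[1] == pytest.approx(0.0, abs=1e-20)

    def test_unit_branch_value(self):
        # closed form: 1 - (2/3) e^{-1}
        assert triple_probabilities(1.0)[0] == pytest.approx(
            1 - 2 / (3 * math.e), abs=1e-12
        )
        assert triple_probabilities(1.0)[0] == pytest.approx(0.7547470, abs=5e-8)

    def test_sums_to_one_and_monotone(self):
        grid = np.linspace(0, 10, 200)
        probs = [triple_probabilities(t) for t in grid]
        assert all(sum(p) == pytest.approx(1.0) for p in probs)
        conc = [p[0] for p in probs]
        assert all(b > a for a, b in zip(conc, conc[1:]))

    def test_negative_length_raises(self):
        with pytest.raises(ValueError):
            triple_probabilities(-0.1)


class TestPseudoLogLikelihood:
    def test_zero_counts_zero_loglik(self):
        table = TripleCountTable(list("ABCDE"))
        tree = parse_newick("((((A,B),C),D),E);")
        for n in tree.postorder():
            if not n.is_leaf and n.parent is not None:
                n.length = 1.0
        assert pseudo_log_likelihood(tree, table) == 0.0

    def test_concordant_counts_approach_zero_for_long_branch(self):
        table = TripleCountTable(list("ABC"))
        table.add_count(("A", "B", "C"), "C", 10)
        tree = parse_newick("((A,B),C);")
        tree.root.children[0].length = 15.0
        ll = pseudo_log_likelihood(tree, table)
        assert -1e-5 < ll < 0.0

    def test_matches_independent_resummation(self, rng):
        """Loop-based multinomial re-summation oracle on random data."""
        species = leaf_names(6)
        sp_tree = random_rooted_tree(rng, species)
        gene_trees = [random_rooted_tree(rng, species) for _ in range(15)]
        table = count_triples(gene_trees, species=species)
        for n in sp_tree.postorder():
            if not n.is_leaf and n.parent is not None:
                n.length = float(rng.uniform(0.1, 3.0))
        ll = pseudo_log_likelihood(sp_tree, table)

        # oracle: per triple, prune the species tree, sum internal path,
        # apply the multinomial log-probability directly
        expected = 0.0
        from redphylo.trees import prune_to

        for taxa in itertools.combinations(sorted(species), 3):
            cnt = table.get_counts(taxa)
            if sum(cnt.values()) == 0:
                continue
            sub = prune_to(sp_tree, set(taxa))
            sets = sub._node_leafsets()
            (cherry_node,) = [
                n for n in sub.postorder() if not n.is_leaf and len(sets[n]) == 2
            ]
            # path length: internal branches between cherry MRCA and triple root
            # in the *unpruned* tree = branch lengths accumulated by pruning
            T = cherry_node.length
            (outlier,) = set(taxa) - sets[cherry_node]
            p_conc, p_disc, _ = triple_probabilities(T)
            for sp, k in cnt.items():
                expected += k * math.log(p_conc if sp == outlier else p_disc)
        assert ll == pytest.approx(expected, rel=1e-9)

    def test_species_absent_from_tree_raises(self):
        table = TripleCountTable(list("ABCD"))
        with pytest.raises(TreeError, match="absent"):
            pseudo_log_likelihood(parse_newick("((A,B),C);"), table)


class TestOptimizeBranchLengths:
    def test_single_branch_closed_form(self):
        table = TripleCountTable(list("ABC"))
        n1, n2, n3 = 7000, 1500, 1500
        table.add_count(("A", "B", "C"), "C", n1)
        table.add_count(("A", "B", "C"), "A", n2)
        table.add_count(("A", "B", "C"), "B", n3)
        est = optimize_branch_lengths(parse_newick("((A,B),C);"), table)
        closed = -math.log(1.5 * (1 - n1 / (n1 + n2 + n3)))
        (tau,) = est.branch_lengths.values()
        assert tau == pytest.approx(closed, abs=1e-5)

    def test_closed_form_matches_grid_search(self):
        table = TripleCountTable(list("ABC"))
        table.add_count(("A", "B", "C"), "C", 7548)
        table.add_count(("A", "B", "C"), "A", 1226)
        table.add_count(("A", "B", "C"), "B", 1226)
        grid = np.linspace(0.5, 1.5, 100001)
        n1, nd = 7548, 2452
        ll = n1 * np.log(1 - (2 / 3) * np.exp(-grid)) + nd * (
            np.log(1 / 3) - grid
        )
        best = grid[np.argmax(ll)]
        closed = invert_concordance(0.7548)
        assert best == pytest.approx(closed, abs=1e-4)

    def test_uniform_counts_drive_tau_to_lower_bound(self):
        table = TripleCountTable(list("ABC"))
        for sp in "ABC":
            table.add_count(("A", "B", "C"), sp, 500)
        est = optimize_branch_lengths(parse_newick("((A,B),C);"), table)
        (tau,) = est.branch_lengths.values()
        assert tau < 1e-4

    def test_optimum_beats_local_perturbations(self, rng):
        species = leaf_names(6)
        sp_tree = random_rooted_tree(rng, species)
        gene_trees = [random_rooted_tree(rng, species) for _ in range(40)]
        table = count_triples(gene_trees, species=species)
        est = optimize_branch_lengths(sp_tree, table)
        for clade, tau in est.branch_lengths.items():
            for factor in (0.9, 1.1):
                perturbed = est.tree.copy()
                sets = perturbed._node_leafsets()
                for n in perturbed.postorder():
                    if not n.is_leaf and n.parent is not None and sets[n] == clade:
                        n.length = max(tau * factor, 1e-8)
                assert (
                    pseudo_log_likelihood(perturbed, table)
                    <= est.log_pseudo_likelihood + 1e-7
                )

    def test_non_binary_topology_rejected(self):
        table = TripleCountTable(list("ABCD"))
        table.add_count(("A", "B", "C"), "C", 5)
        with pytest.raises(TreeError):
            optimize_branch_lengths(parse_newick("((A,B),C,D);"), table)


def _insertions(t, leaf):
    """All ways to insert a leaf into a nested-tuple tree (incl. above root)."""
    yield (t, leaf)
    if isinstance(t, tuple):
        a, b = t
        for s in _insertions(a, leaf):
            yield (s, b)
        for s in _insertions(b, leaf):
            yield (a, s)


def _all_rooted_topologies(labels):
    """Enumerate all (2n-3)!! rooted binary topologies by leaf insertion."""
    trees = [(labels[0], labels[1])]
    for leaf in labels[2:]:
        trees = [new for t in trees for new in _insertions(t, leaf)]
    return trees


def _tuples_to_newick(t):
    if isinstance(t, str):
        return t
    return "(" + _tuples_to_newick(t[0]) + "," + _tuples_to_newick(t[1]) + ")"


class TestSearch:
    def test_expectation_counts_make_truth_a_local_optimum(self):
        """Brute force over all 105 rooted 5-taxon topologies."""
        truth = parse_newick("(((A,B),C),(D,E));")
        for n in truth.postorder():
            if not n.is_leaf and n.parent is not None:
                n.length = 1.2
        species = list("ABCDE")
        table = TripleCountTable(species)
        # expected counts under the MSC for N=3000 genes per triple
        from redphylo.trees import prune_to

        N = 3000
        for taxa in itertools.combinations(species, 3):
            sub = prune_to(truth, set(taxa))
            sets = sub._node_leafsets()
            (cherry_node,) = [
                n for n in sub.postorder() if not n.is_leaf and len(sets[n]) == 2
            ]
            (outlier,) = set(taxa) - sets[cherry_node]
            p_conc, p_disc, _ = triple_probabilities(cherry_node.length)
            for sp in taxa:
                table.add_count(taxa, sp, N * (p_conc if sp == outlier else p_disc))

        topos = _all_rooted_topologies(species)
        assert len(topos) == 105
        best_ll, best_topo = -np.inf, None
        for t in topos:
            tree = parse_newick(_tuples_to_newick(t) + ";")
            est = optimize_branch_lengths(tree, table)
            if est.log_pseudo_likelihood > best_ll:
                best_ll, best_topo = est.log_pseudo_likelihood, tree
        assert rf_distance(best_topo, truth) == 0

        found = search_species_tree(table, n_restarts=2, seed=1)
        assert rf_distance(found.tree, truth) == 0
        assert found.log_pseudo_likelihood == pytest.approx(best_ll, abs=1e-6)

    def test_true_start_is_fixed_point(self, rng, species_tree_15):
        from redphylo.simulate import simulate_msc_gene_trees
        from redphylo.datasets import red_algal_species_tree

        gts = simulate_msc_gene_trees(red_algal_species_tree(), 200, seed=9)
        table = count_triples(gts)
        est = search_species_tree(table, start=species_tree_15, n_restarts=1, seed=0)
        assert rf_distance(est.tree, species_tree_15) == 0

    def test_search_never_worse_than_start(self, rng):
        species = leaf_names(7)
        gene_trees = [random_rooted_tree(rng, species) for _ in range(25)]
        table = count_triples(gene_trees, species=species)
        start = random_rooted_tree(rng, species)
        start_ll = optimize_branch_lengths(start, table).log_pseudo_likelihood
        est = search_species_tree(table, start=start, n_restarts=1, seed=0)
        assert est.log_pseudo_likelihood >= start_ll - 1e-9

    def test_too_few_species_raises(self):
        with pytest.raises(TreeError):
            search_species_tree(TripleCountTable(list("ABC")))

    def test_deterministic_given_seed(self, rng):
        species = leaf_names(6)
        gene_trees = [random_rooted_tree(rng, species) for _ in range(30)]
        table = count_triples(gene_trees, species=species)
        a = search_species_tree(table, n_restarts=4, seed=7)
        b = search_species_tree(table, n_restarts=4, seed=7)
        assert canonical_newick(a.tree) == canonical_newick(b.tree)
        assert a.log_pseudo_likelihood == b.log_pseudo_likelihood


class TestEstimatorAPI:
    def test_fit_sets_trailing_underscore_attributes(self, rng):
        from redphylo.simulate import simulate_msc_gene_trees
        from redphylo.datasets import red_algal_species_tree, RED_ALGAL_TOPOLOGY

        gts = simulate_msc_gene_trees(red_algal_species_tree(), 150, seed=2)
        model = MPEST(n_restarts=2, random_state=0)
        model.fit(gts)
        assert rf_distance(model.species_tree_, parse_newick(RED_ALGAL_TOPOLOGY)) == 0
        assert model.log_pseudo_likelihood_ < 0
        assert all(v >= 0 for v in model.branch_lengths_.values())

    def test_get_params_round_trip(self):
        model = MPEST(n_restarts=5, random_state=3)
        params = model.get_params()
        assert params == {"n_restarts": 5, "random_state": 3}
        clone = MPEST(**params)
        assert clone.get_params() == params
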