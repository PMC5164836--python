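"""Species-tree estimation by maximum pseudo-likelihood over rooted triples.

Under the multispecies coalescent (MSC), a rooted species triple whose
internal path length is ``T`` coalescent units yields the concordant
gene-tree resolution with probability ``1 - (2/3) exp(-T)`` and each of
the two discordant resolutions with probability ``(1/3) exp(-T)``.  The
per-triple counts of the three resolutions over a collection of rooted
gene trees are therefore a sufficient statistic, and the species tree is
estimated by maximising the product of per-triple multinomial likelihoods
(the MP-EST pseudo-likelihood) over rooted topologies and internal branch
lengths.

Only internal branch lengths are estimable from triples; terminal
branches are reported as absent.  Constant multinomial coefficients are
omitted from the objective.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from sklearn.base import BaseEstimator

from .trees import (
    Node,
    RootedTree,
    TreeError,
    canonical_newick,
    write_newick,
)

TAU_MIN = 1e-8
TAU_MAX = 20.0
_IMPROVE_EPS = 1e-8


# ---------------------------------------------------------------------------
# Triple counts
# ---------------------------------------------------------------------------

class TripleCountTable:
    """Counts of the three rooted resolutions for every species triple.

    For the sorted triple ``(a, b, c)`` the three columns count the gene
    trees in which, respectively, ``a``, ``b`` or ``c`` is the *outlier*
    (the species splitting off first).
    """

    def __init__(self, species: list[str]):
        self.species = sorted(species)
        self.index = {s: i for i, s in enumerate(self.species)}
        self.triples = np.array(
            list(itertools.combinations(range(len(self.species)), 3)), dtype=int
        ).reshape(-1, 3)
        self.counts = np.zeros((len(self.triples), 3), dtype=float)
        self._row = {tuple(t): r for r, t in enumerate(map(tuple, self.triples))}

    @property
    def n_species(self) -> int:
        return len(self.species)

    def totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def add_count(self, taxa: tuple[str, str, str], outlier: str, n: float = 1) -> None:
        a, b, c = sorted(taxa)
        row = self._row[(self.index[a], self.index[b], self.index[c])]
        self.counts[row, (a, b, c).index(outlier)] += n

    def get_counts(self, taxa: tuple[str, str, str]) -> dict[str, float]:
        """Counts keyed by outlier species for one triple."""
        a, b, c = sorted(taxa)
        row = self._row[(self.index[a], self.index[b], self.index[c])]
        return {t: self.counts[row, k] for k, t in enumerate((a, b, c))}


def count_triples(
    gene_trees, species: list[str] | None = None
) -> TripleCountTable:
    """Tally rooted-triple resolutions over a collection of rooted gene trees.

    Each gene tree contributes one count to exactly one resolution for every
    species triple it contains; triples involving species absent from a gene
    are untouched.  Raises on duplicate species labels within one gene tree.
    """
    gene_trees = list(gene_trees)
    if species is None:
        seen: set[str] = set()
        for t in gene_trees:
            seen.update(t.leaf_labels())
        species = sorted(seen)
    table = TripleCountTable(species)
    ns = table.n_species
    ia, ib, ic = table.triples[:, 0], table.triples[:, 1], table.triples[:, 2]

    for tree in gene_trees:
        labels = tree.leaf_labels()
        if len(set(labels)) != len(labels):
            raise TreeError("duplicate species label within one gene tree")
        D = _mrca_depth_matrix(tree, table.index, ns)
        dab = D[ia, ib]
        dac = D[ia, ic]
        dbc = D[ib, ic]
        present = (dab >= 0) & (dac >= 0) & (dbc >= 0)
        # outlier = species whose two pairings are the *shallower* MRCAs,
        # i.e. the remaining pair's MRCA is strictly deepest.
        a_out = present & (dbc > dab) & (dbc > dac)
        b_out = present & (dac > dab) & (dac > dbc)
        c_out = present & (dab > dac) & (dab > dbc)
        table.counts[a_out, 0] += 1
        table.counts[b_out, 1] += 1
        table.counts[c_out, 2] += 1
    return table


def _mrca_depth_matrix(tree: RootedTree, index: dict[str, int], ns: int) -> np.ndarray:
    """Pairwise MRCA topological depths for one gene tree; -1 where absent."""
    D = np.full((ns, ns), -1, dtype=int)
    depth = {id(tree.root): 0}
    for node in tree.preorder():
        for c in node.children:
            depth[id(c)] = depth[id(node)] + 1
    leaf_idx: dict[int, list[int]] = {}
    for node in tree.postorder():
        if node.is_leaf:
            leaf_idx[id(node)] = [index[node.label]] if node.label in index else []
        else:
            kids = [leaf_idx[id(c)] for c in node.children]
            d = depth[id(node)]
            for i in range(len(kids)):
                for j in range(i + 1, len(kids)):
                    for x in kids[i]:
                        for y in kids[j]:
                            D[x, y] = D[y, x] = d
            leaf_idx[id(node)] = [x for k in kids for x in k]
    return D


# ---------------------------------------------------------------------------
# MSC triple probabilities
# ---------------------------------------------------------------------------

def triple_probabilities(T: float) -> tuple[float, float, float]:
    """(p_concordant, p_discordant, p_discordant) for internal path length T.

    ``p_concordant = 1 - (2/3) exp(-T)``; the probabilities sum to one and
    reduce to (1/3, 1/3, 1/3) at T = 0 (a star triple).
    """
    if T < 0:
        raise ValueError(f"coalescent path length must be >= 0, got {T}")
    e = np.exp(-T)
    return (1.0 - (2.0 / 3.0) * e, e / 3.0, e / 3.0)


def invert_concordance(p_concordant: float) -> float:
    """Closed-form T with ``1 - (2/3) e^{-T} = p_concordant`` (p > 1/3)."""
    if not (1.0 / 3.0 < p_concordant <= 1.0):
        raise ValueError("concordant probability must lie in (1/3, 1]")
    return -np.log(1.5 * (1.0 - p_concordant))


# ---------------------------------------------------------------------------
# Pseudo-likelihood on a species tree
# ---------------------------------------------------------------------------

@dataclass
class _Design:
    """Per-topology structure mapping internal branches to triple paths."""

    edges: list[Node]               # internal non-root nodes (branch above each)
    M: np.ndarray                   # (n_triples, n_edges) 0/1 path matrix
    conc_col: np.ndarray            # which count column is concordant per triple
    n_conc: np.ndarray              # concordant counts
    n_disc: np.ndarray              # summed discordant counts
    active: np.ndarray              # triples with a positive total count


def _build_design(topology: RootedTree, table: TripleCountTable) -> _Design:
    if not topology.is_binary():
        raise TreeError("species tree must be binary")
    labels = topology.label_set()
    missing = set(table.species) - labels
    if missing:
        raise TreeError(f"species in counts absent from tree: {sorted(missing)}")

    idx = table.index
    ns = table.n_species
    sets = topology._node_leafsets()
    edges = [n for n in topology.postorder() if not n.is_leaf and n.parent is not None]
    C = np.zeros((len(edges), ns), dtype=bool)
    for e, node in enumerate(edges):
        for lab in sets[node]:
            if lab in idx:
                C[e, idx[lab]] = True

    ia, ib, ic = table.triples[:, 0], table.triples[:, 1], table.triples[:, 2]
    in_a, in_b, in_c = C[:, ia], C[:, ib], C[:, ic]
    # column k of the count table = species k is the outlier; the path edges
    # are those whose clade contains the cherry pair but not the outlier.
    masks = np.stack(
        [
            in_b & in_c & ~in_a,
            in_a & in_c & ~in_b,
            in_a & in_b & ~in_c,
        ]
    )  # (3, n_edges, n_triples)
    has_path = masks.any(axis=1)  # (3, n_triples)
    conc_col = has_path.argmax(axis=0)
    if not (has_path.sum(axis=0) == 1).all():
        raise TreeError("species tree does not resolve every triple (non-binary?)")
    m = len(table.triples)
    M = masks[conc_col, :, np.arange(m)].astype(float)  # (m, n_edges)
    n_conc = table.counts[np.arange(m), conc_col]
    n_tot = table.counts.sum(axis=1)
    return _Design(
        edges=edges,
        M=M,
        conc_col=conc_col,
        n_conc=n_conc,
        n_disc=n_tot - n_conc,
        active=n_tot > 0,
    )


_LOG13 = np.log(1.0 / 3.0)


def _neg_ll_and_grad(tau: np.ndarray, design: _Design) -> tuple[float, np.ndarray]:
    T = design.M @ tau
    e = np.exp(-T)
    p_conc = 1.0 - (2.0 / 3.0) * e
    act = design.active
    ll = np.sum(design.n_conc[act] * np.log(p_conc[act])) + np.sum(
        design.n_disc[act] * (_LOG13 - T[act])
    )
    dT = np.zeros_like(T)
    dT[act] = design.n_conc[act] * (2.0 / 3.0) * e[act] / p_conc[act] - design.n_disc[act]
    return -ll, -(design.M.T @ dT)


def pseudo_log_likelihood(tree: RootedTree, counts: TripleCountTable) -> float:
    """MP-EST pseudo-log-likelihood of a species tree with branch lengths.

    Internal branch lengths are read off the tree (missing lengths count as
    TAU_MIN); triples with zero total count contribute zero.
    """
    design = _build_design(tree, counts)
    tau = np.array(
        [n.length if n.length is not None else TAU_MIN for n in design.edges]
    )
    if (tau < 0).any():
        raise TreeError("negative internal branch length")
    return -_neg_ll_and_grad(np.maximum(tau, TAU_MIN), design)[0]


@dataclass
class SpeciesTreeEstimate:
    """A species-tree topology with optimised coalescent branch lengths."""

    tree: RootedTree
    log_pseudo_likelihood: float
    branch_lengths: dict[frozenset[str], float] = field(default_factory=dict)

    def newick(self) -> str:
        return write_newick(self.tree)


def optimize_branch_lengths(
    topology: RootedTree,
    counts: TripleCountTable,
    x0: np.ndarray | None = None,
) -> SpeciesTreeEstimate:
    """Maximise the pseudo-likelihood over internal branch lengths.

    Bounded L-BFGS-B with analytic gradient; bounds [1e-8, 20] coalescent
    units, objective tolerance 1e-6.  Terminal branch lengths are not
    estimable from triples and are left absent.
    """
    design = _build_design(topology, counts)
    k = len(design.edges)
    if x0 is None or len(x0) != k:
        x0 = np.full(k, 1.0)
    res = minimize(
        _neg_ll_and_grad,
        np.clip(x0, TAU_MIN, TAU_MAX),
        args=(design,),
        jac=True,
        method="L-BFGS-B",
        bounds=[(TAU_MIN, TAU_MAX)] * k,
        options={"ftol": 1e-10, "gtol": 1e-8, "maxiter": 500},
    )
    fitted = topology.copy()
    fdesign = _build_design(fitted, counts)
    sets = fitted._node_leafsets()
    lengths: dict[frozenset[str], float] = {}
    for node, tau in zip(fdesign.edges, res.x):
        node.length = float(tau)
        lengths[sets[node]] = float(tau)
    for node in fitted.postorder():
        if node.is_leaf or node.parent is None:
            node.length = None
    return SpeciesTreeEstimate(
        tree=fitted, log_pseudo_likelihood=float(-res.fun), branch_lengths=lengths
    )


# ---------------------------------------------------------------------------
# Topology search
# ---------------------------------------------------------------------------

def _rooted_nni_neighbors(tree: RootedTree) -> list[RootedTree]:
    """All rooted NNI rearrangements (2 per internal non-root branch)."""
    neighbors = []
    nodes = [n for n in tree.postorder() if not n.is_leaf and n.parent is not None]
    paths = {id(n): p for p, n in enumerate(tree.postorder())}
    order = list(tree.postorder())
    for target_pos, _ in [(paths[id(n)], n) for n in nodes]:
        for swap in (0, 1):
            clone = tree.copy()
            clone_order = list(clone.postorder())
            u = clone_order[target_pos]
            v = u.parent
            sib = v.children[0] if v.children[1] is u else v.children[1]
            child = u.children[swap]
            # exchange `child` (under u) with `sib` (under v)
            u.children[u.children.index(child)] = sib
            sib.parent = u
            v.children[v.children.index(sib)] = child
            child.parent = v
            neighbors.append(clone)
    return neighbors


def _triplet_agglomeration_start(counts: TripleCountTable) -> RootedTree:
    """Deterministic start topology by concordance-weighted agglomeration.

    Pairwise weight w(x, y) = fraction of counted triples containing x and y
    in which {x, y} is the cherry; clusters are merged greedily by the mean
    cross-pair weight (ties broken lexicographically).
    """
    ns = counts.n_species
    conc = np.zeros((ns, ns))
    tot = np.zeros((ns, ns))
    ia, ib, ic = counts.triples[:, 0], counts.triples[:, 1], counts.triples[:, 2]
    n = counts.counts
    t = n.sum(axis=1)
    # counts column k = species k is the outlier => cherry is the other pair
    np.add.at(conc, (ib, ic), n[:, 0])
    np.add.at(conc, (ia, ic), n[:, 1])
    np.add.at(conc, (ia, ib), n[:, 2])
    for pair in ((ia, ib), (ia, ic), (ib, ic)):
        np.add.at(tot, pair, t)
    with np.errstate(invalid="ignore", divide="ignore"):
        W = np.where(tot > 0, conc / np.maximum(tot, 1), 0.0)
    W = W + W.T

    clusters: list[tuple[list[int], Node]] = [
        ([i], Node(label=s)) for i, s in enumerate(counts.species)
    ]
    while len(clusters) > 1:
        best = None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                xi, xj = clusters[i][0], clusters[j][0]
                score = W[np.ix_(xi, xj)].mean()
                key = (-score, counts.species[min(xi)], counts.species[min(xj)])
                if best is None or key < best[0]:
                    best = (key, i, j)
        _, i, j = best
        (mi, ni), (mj, nj) = clusters[i], clusters[j]
        parent = Node()
        parent.add_child(ni)
        parent.add_child(nj)
        merged = ([*mi, *mj], parent)
        clusters = [c for k, c in enumerate(clusters) if k not in (i, j)]
        clusters.append(merged)
    return RootedTree(clusters[0][1])


def _strip_lengths(tree: RootedTree) -> RootedTree:
    out = tree.copy()
    for node in out.postorder():
        node.length = None
        node.support = None
    return out


def _hill_climb(
    start: RootedTree,
    counts: TripleCountTable,
    cache: dict[str, SpeciesTreeEstimate],
) -> SpeciesTreeEstimate:
    def evaluate(topology: RootedTree, warm: np.ndarray | None) -> SpeciesTreeEstimate:
        key = canonical_newick(topology)
        if key not in cache:
            cache[key] = optimize_branch_lengths(topology, counts, x0=warm)
        return cache[key]

    current = evaluate(start, None)
    warm = None
    while True:
        best_neighbor = None
        best_key = None
        cur_topo = _strip_lengths(current.tree)
        tau = np.array(list(current.branch_lengths.values())) if current.branch_lengths else None
        for nb in _rooted_nni_neighbors(cur_topo):
            est = evaluate(nb, tau)
            if est.log_pseudo_likelihood > current.log_pseudo_likelihood + _IMPROVE_EPS:
                key = (-est.log_pseudo_likelihood, canonical_newick(est.tree))
                if best_neighbor is None or key < best_key:
                    best_neighbor, best_key = est, key
        if best_neighbor is None:
            return current
        current = best_neighbor


def search_species_tree(
    counts: TripleCountTable,
    start: RootedTree | None = None,
    n_restarts: int = 10,
    seed: int = 0,
) -> SpeciesTreeEstimate:
    """Hill-climbing maximum pseudo-likelihood search over rooted topologies.

    Climbs the rooted-NNI neighbourhood from a deterministic
    concordance-agglomeration start tree (or ``start``), accepting the best
    neighbour whenever it improves the optimised objective by more than
    1e-8; additional restarts perturb the start by 3 random NNI moves.
    Deterministic given ``seed``; ties resolved toward the
    lexicographically smallest canonical Newick.
    """
    if counts.n_species < 4:
        raise TreeError("species-tree search needs counts covering >= 4 species")
    rng = np.random.default_rng(seed)
    cache: dict[str, SpeciesTreeEstimate] = {}
    base = _strip_lengths(start) if start is not None else _triplet_agglomeration_start(counts)
    if start is not None and set(base.leaf_labels()) != set(counts.species):
        raise TreeError("start tree must cover exactly the counted species")

    best = _hill_climb(base, counts, cache)
    for _ in range(max(0, n_restarts - 1)):
        perturbed = base
        for _k in range(3):
            nbs = _rooted_nni_neighbors(perturbed)
            perturbed = nbs[rng.integers(len(nbs))]
        est = _hill_climb(perturbed, counts, cache)
        if est.log_pseudo_likelihood > best.log_pseudo_likelihood + _IMPROVE_EPS or (
            abs(est.log_pseudo_likelihood - best.log_pseudo_likelihood) <= _IMPROVE_EPS
            and canonical_newick(est.tree) < canonical_newick(best.tree)
        ):
            best = est
    return best


# ---------------------------------------------------------------------------
# Estimator front-end
# ---------------------------------------------------------------------------

class MPEST(BaseEstimator):
    """Maximum pseudo-likelihood species-tree estimator (MP-EST).

    Parameters
    ----------
    n_restarts : int
        Hill-climbing restarts; the first climb starts from a deterministic
        concordance-agglomeration tree, the rest from random 3-NNI
        perturbations of it.
    random_state : int
        Seed for the restart perturbations.

    Attributes (after ``fit``)
    --------------------------
    species_tree_ : RootedTree
        Estimated rooted topology with internal branch lengths in
        coalescent units.
    log_pseudo_likelihood_ : float
    branch_lengths_ : dict mapping each internal clade (frozenset of
        species) to its coalescent-unit branch length.
    counts_ : TripleCountTable
    """

    def __init__(self, n_restarts: int = 10, random_state: int = 0):
        self.n_restarts = n_restarts
        self.random_state = random_state

    def fit(self, X, y=None, start: RootedTree | None = None):
        """Fit from rooted gene trees (sequence of RootedTree) or a count table."""
        counts = X if isinstance(X, TripleCountTable) else count_triples(X)
        est = search_species_tree(
            counts, start=start, n_restarts=self.n_restarts, seed=self.random_state
        )
        self.counts_ = counts
        self.species_tree_ = est.tree
        self.log_pseudo_likelihood_ = est.log_pseudo_likelihood
        self.branch_lengths_ = est.branch_lengths
        return self

    def score(self, X=None, y=None) -> float:
        return self.log_pseudo_likelihood_
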