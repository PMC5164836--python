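"""Two-level nonparametric bootstrap for coalescent species-tree support.

Each replicate resamples genes with replacement, then sites (columns)
within every sampled gene with replacement, so both gene-sampling and
site-sampling uncertainty propagate into the species tree.  Per
replicate, each pseudo-alignment is reduced to a single green outgroup
row, a gene tree is estimated (neighbor joining on Poisson-corrected
protein distances by default; an external backend is pluggable), rooted
on the outgroup, and the replicate species tree is found by maximum
pseudo-likelihood.  Replicates are summarised by majority rule after
pruning to the red-algal taxa.
"""

from __future__ import annotations

import subprocess
import tempfile
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from skbio import DistanceMatrix
from skbio.tree import nj
from sklearn.base import BaseEstimator

from .mpest import count_triples, search_species_tree
from .orthologs import (
    DEFAULT_OUTGROUP_PRIORITY,
    GeneAlignment,
    TaxonTable,
    reduce_outgroup,
)
from .trees import (
    RootedTree,
    majority_rule_consensus,
    parse_newick,
    prune_to,
    root_with_outgroup,
    write_newick,
)

MAX_DISTANCE = 10.0
_GAP_CODES = frozenset(b"-X")


class BootstrapError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# Resampling
# ---------------------------------------------------------------------------

def resample_genes(alignments, seed: int) -> list[GeneAlignment]:
    """Sample ``len(alignments)`` genes uniformly with replacement."""
    alignments = list(alignments)
    if not alignments:
        raise ValueError("cannot resample an empty gene list")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, len(alignments), size=len(alignments))
    return [alignments[i] for i in idx]


def resample_sites(alignment: GeneAlignment, seed: int) -> GeneAlignment:
    """Pseudo-alignment: columns drawn uniformly with replacement.

    Columns are copied jointly across rows, preserving within-column
    linkage; row ids and the column count are unchanged.
    """
    if alignment.n_columns == 0:
        raise ValueError(f"alignment {alignment.gene_id} has no columns")
    rng = np.random.default_rng(seed)
    cols = rng.integers(0, alignment.n_columns, size=alignment.n_columns)
    mat = _as_matrix(alignment)[:, cols]
    rows = [
        (rid, mat[i].tobytes().decode())
        for i, (rid, _) in enumerate(alignment.rows)
    ]
    return GeneAlignment(alignment.gene_id, rows)


def _as_matrix(alignment: GeneAlignment) -> np.ndarray:
    return np.frombuffer(
        "".join(seq for _, seq in alignment.rows).encode(), dtype=np.uint8
    ).reshape(alignment.n_rows, alignment.n_columns)


# ---------------------------------------------------------------------------
# Gene-tree estimation (internal backend)
# ---------------------------------------------------------------------------

def poisson_distances(alignment: GeneAlignment) -> np.ndarray:
    """Pairwise Poisson-corrected distances d = -ln(1 - p).

    p is the mismatch proportion over columns where both rows are non-gap
    ('-' and 'X' excluded).  Pairs with no shared columns, or p >= 1, are
    capped at MAX_DISTANCE with a warning.
    """
    mat = _as_matrix(alignment)
    ok = (mat != ord("-")) & (mat != ord("X"))
    n = alignment.n_rows
    D = np.zeros((n, n))
    capped = False
    for i in range(n):
        for j in range(i + 1, n):
            both = ok[i] & ok[j]
            shared = int(both.sum())
            if shared == 0:
                D[i, j] = D[j, i] = MAX_DISTANCE
                capped = True
                continue
            p = float((mat[i, both] != mat[j, both]).sum()) / shared
            if p >= 1.0:
                d = MAX_DISTANCE
                capped = True
            else:
                d = min(-np.log(1.0 - p), MAX_DISTANCE)
            D[i, j] = D[j, i] = d
    if capped:
        warnings.warn(
            f"alignment {alignment.gene_id}: saturated or non-overlapping pairs; "
            f"distance capped at {MAX_DISTANCE}",
            stacklevel=2,
        )
    return D


def estimate_gene_tree(alignment: GeneAlignment, outgroup) -> RootedTree:
    """Neighbor joining on Poisson-corrected distances, rooted on ``outgroup``.

    Substitutes for per-gene maximum-likelihood inference; leaf labels are
    the alignment row ids.  Negative NJ branch lengths are clamped to zero.
    """
    if alignment.n_rows < 3:
        raise ValueError("gene-tree estimation needs at least 3 sequences")
    ids = [rid for rid, _ in alignment.rows]
    missing = set(outgroup) - set(ids)
    if missing:
        raise ValueError(f"outgroup rows absent from alignment: {sorted(missing)}")
    dm = DistanceMatrix(poisson_distances(alignment), ids=ids)
    tree = parse_newick(str(nj(dm)).strip(), support_labels=False)
    for node in tree.postorder():
        if node.length is not None and node.length < 0:
            node.length = 0.0
    tree = RootedTree(tree.root)
    return root_with_outgroup(tree, outgroup)


def _command_backend(template: str):
    """Build a gene-tree backend from a shell template.

    The template must contain ``{fasta}`` and ``{tree}`` placeholders; the
    command must write one Newick tree to ``{tree}``.
    """

    def backend(alignment: GeneAlignment, outgroup) -> RootedTree:
        with tempfile.TemporaryDirectory() as tmp:
            fasta = Path(tmp) / "gene.fasta"
            treefile = Path(tmp) / "gene.nwk"
            alignment.to_fasta(str(fasta))
            cmd = template.format(fasta=fasta, tree=treefile)
            proc = subprocess.run(cmd, shell=True, capture_output=True, text=True)
            if proc.returncode != 0:
                raise BootstrapError(
                    f"gene-tree command failed ({proc.returncode}): {proc.stderr[:500]}"
                )
            tree = parse_newick(treefile.read_text().strip())
            for node in tree.postorder():
                if node.length is not None and node.length < 0:
                    node.length = 0.0
            return root_with_outgroup(tree, outgroup)

    return backend


# ---------------------------------------------------------------------------
# The bootstrap itself
# ---------------------------------------------------------------------------

@dataclass
class BootstrapResult:
    replicate_trees: list[RootedTree]
    consensus: RootedTree
    supports: dict[frozenset, float]
    provenance: dict = field(default_factory=dict)


def _replicate_seed(master: int, replicate: int, gene: int | None = None) -> int:
    key = (replicate,) if gene is None else (replicate, gene)
    ss = np.random.SeedSequence(master, spawn_key=key)
    return int(ss.generate_state(1)[0] % (2**31))


def run_bootstrap(
    alignments,
    taxa: TaxonTable,
    n_replicates: int = 100,
    seed: int = 0,
    gene_tree_backend="internal",
    outgroup_priority=DEFAULT_OUTGROUP_PRIORITY,
    n_restarts: int = 2,
    consensus_mode: str = "extended",
    do_resample_genes: bool = True,
    do_resample_sites: bool = True,
) -> BootstrapResult:
    """Run the two-level (gene + site) species-tree bootstrap.

    Gene- and site-level random streams are derived from the master seed
    by replicate and gene indices, so each replicate is individually
    reproducible.  A failing replicate is skipped and logged; the run
    aborts if more than 10% of replicates fail.
    """
    alignments = list(alignments)
    if not alignments:
        raise ValueError("no alignments supplied")
    if isinstance(gene_tree_backend, str) and gene_tree_backend != "internal":
        backend = _command_backend(gene_tree_backend)
    elif callable(gene_tree_backend):
        backend = gene_tree_backend
    else:
        backend = estimate_gene_tree

    red = set(taxa.red_taxa())
    replicate_trees: list[RootedTree] = []
    failures: list[dict] = []
    for r in range(n_replicates):
        try:
            if do_resample_genes:
                sample = resample_genes(alignments, _replicate_seed(seed, r))
            else:
                sample = alignments
            gene_trees = []
            for g, aln in enumerate(sample):
                if do_resample_sites:
                    aln = resample_sites(aln, _replicate_seed(seed, r, g))
                aln = reduce_outgroup(aln, outgroup_priority)
                aln = aln.relabel_to_taxa()
                og = [t for t in aln.taxa() if t in outgroup_priority]
                gene_trees.append(backend(aln, og))
            counts = count_triples(gene_trees)
            est = search_species_tree(
                counts, n_restarts=n_restarts, seed=_replicate_seed(seed, r)
            )
            pruned = prune_to(est.tree, set(est.tree.leaf_labels()) & red)
            replicate_trees.append(pruned)
        except Exception as exc:  # noqa: BLE001 - replicate-level containment
            failures.append({"replicate": r, "error": f"{type(exc).__name__}: {exc}"})
    if len(failures) > 0.1 * n_replicates:
        raise BootstrapError(
            f"{len(failures)}/{n_replicates} replicates failed: {failures[:3]}"
        )
    consensus = majority_rule_consensus(replicate_trees, mode=consensus_mode)
    supports = _clade_supports(consensus)
    return BootstrapResult(
        replicate_trees=replicate_trees,
        consensus=consensus,
        supports=supports,
        provenance={
            "seed": seed,
            "n_replicates": n_replicates,
            "n_failed": len(failures),
            "failures": failures,
            "consensus_mode": consensus_mode,
            "backend": "internal" if backend is estimate_gene_tree else "external",
            "consensus_newick": write_newick(consensus),
        },
    )


def _clade_supports(consensus: RootedTree) -> dict[frozenset, float]:
    sets = consensus._node_leafsets()
    n = consensus.n_leaves
    return {
        sets[node]: node.support
        for node in consensus.postorder()
        if not node.is_leaf
        and node.parent is not None
        and node.support is not None
        and 2 <= len(sets[node]) < n
    }


class TwoLevelBootstrap(BaseEstimator):
    """Sklearn-style front end for the gene+site species-tree bootstrap.

    Attributes after ``fit(alignments, taxa=...)``: ``replicate_trees_``,
    ``consensus_tree_``, ``supports_`` (clade -> percentage) and
    ``provenance_``.
    """

    def __init__(
        self,
        n_replicates: int = 100,
        random_state: int = 0,
        gene_tree_backend="internal",
        n_restarts: int = 2,
        consensus_mode: str = "extended",
    ):
        self.n_replicates = n_replicates
        self.random_state = random_state
        self.gene_tree_backend = gene_tree_backend
        self.n_restarts = n_restarts
        self.consensus_mode = consensus_mode

    def fit(self, X, y=None, taxa: TaxonTable | None = None):
        if taxa is None:
            raise ValueError("fit requires taxa=TaxonTable")
        result = run_bootstrap(
            X,
            taxa,
            n_replicates=self.n_replicates,
            seed=self.random_state,
            gene_tree_backend=self.gene_tree_backend,
            n_restarts=self.n_restarts,
            consensus_mode=self.consensus_mode,
        )
        self.replicate_trees_ = result.replicate_trees
        self.consensus_tree_ = result.consensus
        self.supports_ = result.supports
        self.provenance_ = result.provenance
        return self
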