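"""Synthetic data with the statistical structure the pipeline assumes.

Generators for: gene trees drawn from the multispecies coalescent on a
known species tree (coalescent-unit branch lengths, one lineage sampled
per species), protein alignments evolved on those gene trees under an
equal-exchangeability 20-state model, orthogroup tables with planted
filter verdicts, and presence/absence characters with planted loss
events.  Every generator is deterministic given its seed.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .orthologs import AMINO_ACIDS, GeneAlignment, OrthoGroupSet, TaxonTable
from .trees import Node, RootedTree, TreeError

_AA = np.frombuffer("".join(AMINO_ACIDS).encode(), dtype=np.uint8)


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass
class SimulationConfig:
    """Study design for an end-to-end synthetic dataset.

    ``rate`` converts coalescent units to expected substitutions per site
    (default 0.05/unit); missingness rates drop whole taxa from individual
    genes, emulating transcriptome incompleteness.
    """

    species_tree: RootedTree
    n_genes: int = 298
    n_columns: int = 300
    rate: float = 0.05
    missing_rate_red: float = 0.0
    missing_rate_green: float = 0.0
    seed: int = 0

    def __post_init__(self):
        for r in (self.missing_rate_red, self.missing_rate_green):
            if not 0.0 <= r <= 1.0:
                raise ValueError("missingness rates must lie in [0, 1]")
        if self.rate < 0:
            raise ValueError("substitution rate must be >= 0")


# ---------------------------------------------------------------------------
# Multispecies coalescent gene trees
# ---------------------------------------------------------------------------

def _node_ages(tree: RootedTree) -> dict[int, float]:
    """Leaf-up ages; requires an ultrametric tree (equal root-to-leaf depth)."""
    ages: dict[int, float] = {}
    for node in tree.postorder():
        if node.is_leaf:
            ages[id(node)] = 0.0
        else:
            kid_ages = []
            for c in node.children:
                if c.length is None:
                    raise TreeError("species tree must have branch lengths")
                kid_ages.append(ages[id(c)] + c.length)
            if max(kid_ages) - min(kid_ages) > 1e-9 * max(1.0, max(kid_ages)):
                raise TreeError(
                    "species tree must be ultrametric in coalescent units "
                    f"(child ages {kid_ages})"
                )
            ages[id(node)] = kid_ages[0]
    return ages


def simulate_msc_gene_trees(
    species_tree: RootedTree, n_genes: int, seed: int = 0
) -> list[RootedTree]:
    """Draw rooted gene trees from the MSC, one lineage per species.

    Within each species-tree branch of duration ``t`` (coalescent units),
    ``k`` lineages coalesce with exponential waiting times at rate
    k(k-1)/2 truncated at ``t``; surviving lineages coalesce freely in the
    root population.  Gene-tree branch lengths are in coalescent units.
    """
    if not species_tree.is_binary():
        raise TreeError("species tree must be binary")
    ages = _node_ages(species_tree)
    rng = np.random.default_rng(seed)
    order = list(species_tree.postorder())
    out = []
    for _ in range(n_genes):
        active: dict[int, list[tuple[Node, float]]] = {}
        for node in order:
            if node.is_leaf:
                lineages = [(Node(label=node.label), 0.0)]
            else:
                lineages = []
                for c in node.children:
                    lineages.extend(active.pop(id(c)))
            start = ages[id(node)]
            end = np.inf if node.parent is None else start + node.length
            t = start
            while len(lineages) > 1:
                k = len(lineages)
                t += rng.exponential(2.0 / (k * (k - 1)))
                if t > end:
                    break
                i, j = rng.choice(k, size=2, replace=False)
                a, b = lineages[i], lineages[j]
                parent = Node()
                for child, age in (a, b):
                    child.length = t - age
                    parent.add_child(child)
                lineages = [l for m, l in enumerate(lineages) if m not in (i, j)]
                lineages.append((parent, t))
            active[id(node)] = lineages
        ((root, _),) = active[id(species_tree.root)]
        root.length = None
        out.append(RootedTree(root))
    return out


def scale_branch_lengths(tree: RootedTree, rate: float) -> RootedTree:
    """Convert coalescent-unit branch lengths to substitutions/site."""
    out = tree.copy()
    for node in out.postorder():
        if node.length is not None:
            node.length = node.length * rate
    return out


# ---------------------------------------------------------------------------
# Protein alignment simulation
# ---------------------------------------------------------------------------

def substitution_probability(b: float) -> float:
    """Per-site change probability over a branch of length b subs/site.

    Equal-exchangeability 20-state model: (19/20) * (1 - exp(-(20/19) b)).
    """
    return (19.0 / 20.0) * (1.0 - np.exp(-(20.0 / 19.0) * b))


def simulate_alignment(
    gene_tree: RootedTree, n_columns: int, seed: int = 0, gene_id: str = "gene"
) -> GeneAlignment:
    """Evolve an amino-acid alignment along a gene tree.

    The root sequence is uniform over the 20 amino acids; along each branch
    each site substitutes with probability (19/20)(1 - e^{-(20/19) b}) to a
    uniformly chosen different residue.
    """
    rng = np.random.default_rng(seed)
    seqs: dict[int, np.ndarray] = {
        id(gene_tree.root): rng.choice(_AA, size=n_columns)
    }
    rows = []
    for node in gene_tree.preorder():
        if node.parent is not None:
            if node.length is None:
                raise TreeError("gene tree must have branch lengths on all branches")
            parent_seq = seqs[id(node.parent)]
            p = substitution_probability(node.length)
            seq = parent_seq.copy()
            hit = rng.random(n_columns) < p
            n_hit = int(hit.sum())
            if n_hit:
                # uniform over the 19 other residues
                shift = rng.integers(1, 20, size=n_hit)
                cur = np.searchsorted(_AA, seq[hit])
                seq[hit] = _AA[(cur + shift) % 20]
            seqs[id(node)] = seq
        if node.is_leaf:
            rows.append((node.label, seqs[id(node)].tobytes().decode()))
    rows.sort(key=lambda r: r[0])
    return GeneAlignment(gene_id, rows)


# ---------------------------------------------------------------------------
# End-to-end dataset
# ---------------------------------------------------------------------------

def simulate_dataset(
    config: SimulationConfig, taxa: TaxonTable | None = None
) -> dict:
    """Simulate gene trees and alignments on the configured species tree.

    Returns a dict with ``gene_trees`` (coalescent units), ``alignments``
    (one per gene, sequence ids "taxon|taxon_gXXX"), and the config.  When a
    taxon table is given, per-gene missingness drops red/green taxa at the
    configured rates (never below 3 remaining taxa).
    """
    root_seed = np.random.SeedSequence(config.seed)
    tree_seed, aln_seed, miss_seed = root_seed.spawn(3)
    gene_trees = simulate_msc_gene_trees(
        config.species_tree,
        config.n_genes,
        seed=np.random.default_rng(tree_seed).integers(2**31),
    )
    miss_rng = np.random.default_rng(miss_seed)
    aln_rngs = aln_seed.spawn(config.n_genes)
    alignments = []
    kept_trees = []
    for g, tree in enumerate(gene_trees):
        gid = f"g{g:04d}"
        keep = tree.leaf_labels()
        if taxa is not None and (config.missing_rate_red or config.missing_rate_green):
            kept = []
            for lab in keep:
                rate = (
                    config.missing_rate_red
                    if taxa.group_of(lab) == "red"
                    else config.missing_rate_green
                )
                if miss_rng.random() >= rate:
                    kept.append(lab)
            if len(kept) >= 3:
                keep = kept
        from .trees import prune_to

        gtree = prune_to(tree, keep) if set(keep) != set(tree.leaf_labels()) else tree
        scaled = scale_branch_lengths(gtree, config.rate)
        scaled.root.length = None
        aln = simulate_alignment(
            scaled,
            config.n_columns,
            seed=np.random.default_rng(aln_rngs[g]).integers(2**31),
            gene_id=gid,
        )
        aln = GeneAlignment(gid, [(f"{lab}|{lab}_{gid}", seq) for lab, seq in aln.rows])
        alignments.append(aln)
        kept_trees.append(gtree)
    return {
        "config": config,
        "gene_trees": kept_trees,
        "alignments": alignments,
    }


# ---------------------------------------------------------------------------
# Orthogroup fixture with planted filter verdicts
# ---------------------------------------------------------------------------

FIXTURE_CATEGORIES = (
    "clean",
    "multi_copy",
    "red_missing",
    "green_missing",
    "short_alignment",
    "few_sequences",
)


def _random_seqs(rng: np.random.Generator, ids: list[str], n_cols: int):
    return [(i, rng.choice(_AA, size=n_cols).tobytes().decode()) for i in ids]


def generate_orthogroup_fixture(
    taxa: TaxonTable, counts: dict[str, int], seed: int = 0
):
    """Orthogroups + alignments whose filter verdicts are known by construction.

    Categories: ``clean`` single-copy groups passing every filter (the first
    clean group sits exactly on the 151-column / 15-row retention boundary);
    ``multi_copy`` (one taxon contributes two genes); ``red_missing``
    (exactly 4 red taxa absent); ``green_missing`` (2 green taxa absent);
    ``short_alignment`` (exactly 150 columns); ``few_sequences`` (14 rows,
    realised by 3 missing red + 1 missing green, still within the
    missingness allowance).

    Returns (OrthoGroupSet, {group_id: GeneAlignment}, truth records).
    """
    for cat, n in counts.items():
        if cat not in FIXTURE_CATEGORIES:
            raise ValueError(f"unknown fixture category {cat!r}")
        if n < 0:
            raise ValueError("category counts must be >= 0")
    rng = np.random.default_rng(seed)
    red = taxa.red_taxa()
    green = taxa.green_taxa()
    groups: dict[str, list[tuple[str, str]]] = {}
    alignments: dict[str, GeneAlignment] = {}
    truth: list[dict] = []
    gi = 0
    for cat in FIXTURE_CATEGORIES:
        for j in range(counts.get(cat, 0)):
            gid = f"OG{gi:04d}"
            gi += 1
            present = list(red) + list(green)
            n_cols = int(rng.integers(160, 400))
            expected_pass, reason = True, ""
            if cat == "clean" and j == 0:
                # boundary clean group: 151 columns, exactly 15 rows
                present = list(red[:-3]) + list(green)
                n_cols = 151
            elif cat == "multi_copy":
                expected_pass, reason = False, "multi-copy"
            elif cat == "red_missing":
                drop = rng.choice(len(red), size=4, replace=False)
                present = [t for k, t in enumerate(red) if k not in drop] + list(green)
                expected_pass, reason = False, "red-missingness"
            elif cat == "green_missing":
                drop = rng.choice(len(green), size=2, replace=False)
                present = list(red) + [t for k, t in enumerate(green) if k not in drop]
                expected_pass, reason = False, "green-missingness"
            elif cat == "short_alignment":
                n_cols = 150
                expected_pass, reason = False, "short-alignment"
            elif cat == "few_sequences":
                present = list(red[:-3]) + list(green[:-1])
                expected_pass, reason = False, "few-sequences"
            members = [(t, f"{t}_{gid}") for t in present]
            if cat == "multi_copy":
                dup = present[int(rng.integers(len(present)))]
                members.append((dup, f"{dup}_{gid}b"))
            groups[gid] = members
            ids = [f"{t}|{g}" for t, g in members]
            alignments[gid] = GeneAlignment(gid, _random_seqs(rng, ids, n_cols))
            truth.append(
                {
                    "group_id": gid,
                    "category": cat,
                    "expected_pass": expected_pass,
                    "expected_reason": reason,
                    "n_columns": n_cols,
                    "n_rows": len(members),
                }
            )
    return OrthoGroupSet(groups), alignments, truth


# ---------------------------------------------------------------------------
# Presence/absence scenarios with planted losses
# ---------------------------------------------------------------------------

def generate_presence_scenario(
    species_tree: RootedTree,
    loss_edges,
    ambiguous_taxa=(),
    seed: int = 0,
) -> dict[str, str]:
    """Leaf states implied by planting losses on the given disjoint clades.

    Leaves under any planted loss edge are 'absent' (or 'ambiguous' if
    listed in ``ambiguous_taxa``); all other leaves are 'present'.
    """
    labels = species_tree.label_set()
    loss_sets = [frozenset(e) for e in loss_edges]
    clades = set(species_tree.clades(include_trivial=True)) | {
        frozenset([l]) for l in labels
    }
    for s in loss_sets:
        if s not in clades:
            raise TreeError(f"planted loss {sorted(s)} is not a clade of the tree")
    for a, b in itertools.combinations(loss_sets, 2):
        if a & b:
            raise TreeError("planted loss clades overlap")
    ambiguous = frozenset(ambiguous_taxa)
    lost = frozenset().union(*loss_sets) if loss_sets else frozenset()
    if not ambiguous <= lost:
        raise TreeError("ambiguous taxa must lie under a planted loss edge")
    states = {}
    for lab in labels:
        if lab in lost:
            states[lab] = "ambiguous" if lab in ambiguous else "absent"
        else:
            states[lab] = "present"
    return states
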