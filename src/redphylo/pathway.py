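"""Metabolic-pathway presence/absence and Dollo gene-loss mapping.

Candidate orthologs are pulled from BLAST-style hit tables (top bit-score
and top-identity hits per query), validated by monophyly with the
reference species in a gene tree, turned into a gene x taxon presence
matrix, and mapped onto the species tree under Dollo parsimony (a single
gain, unlimited losses; the minimal loss set explains all absences).

Absence in a transcriptome-only taxon is weak evidence — missing data is
common in transcriptomes — so the default policy records it as
'ambiguous'; genome-backed absences are always 'absent'.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .orthologs import TaxonTable
from .trees import RootedTree, TreeError

PRESENT, ABSENT, AMBIGUOUS = "present", "absent", "ambiguous"
_STATE_CODE = {PRESENT: "P", ABSENT: "A", AMBIGUOUS: "?"}
_CODE_STATE = {v: k for k, v in _STATE_CODE.items()}

OUTFMT6_COLUMNS = (
    "qseqid sseqid pident length mismatch gapopen "
    "qstart qend sstart send evalue bitscore"
).split()


# ---------------------------------------------------------------------------
# Hit tables and candidate selection
# ---------------------------------------------------------------------------

def read_hit_table(path) -> pd.DataFrame:
    """Read a BLAST tabular (outfmt-6 column order) TSV.

    The subject taxon is parsed from the prefix of ``sseqid`` before the
    first '|'.
    """
    df = pd.read_csv(path, sep="\t", header=None, names=OUTFMT6_COLUMNS)
    return normalize_hit_table(df)


def normalize_hit_table(df: pd.DataFrame) -> pd.DataFrame:
    df = df.copy()
    if "taxon" not in df.columns:
        df["taxon"] = (
            df["sseqid"].str.partition("|")[0] if len(df) else pd.Series(dtype=str)
        )
    if ((df["pident"] < 0) | (df["pident"] > 100)).any():
        raise ValueError("percent identity outside [0, 100]")
    if (df["bitscore"] <= 0).any():
        raise ValueError("bit scores must be positive")
    if (df["evalue"] < 0).any():
        raise ValueError("e-values must be non-negative")
    return df


def select_candidates(hits: pd.DataFrame, k: int = 3) -> dict[str, set[str]]:
    """Per query: union of the k top-bit-score and k top-identity subjects.

    Ties are broken by ascending subject id, so selection is deterministic.
    An empty table yields an empty dict.
    """
    out: dict[str, set[str]] = {}
    if hits.empty:
        return out
    for query, sub in hits.groupby("qseqid"):
        by_bits = sub.sort_values(
            ["bitscore", "sseqid"], ascending=[False, True]
        ).drop_duplicates("sseqid")
        by_ident = sub.sort_values(
            ["pident", "sseqid"], ascending=[False, True]
        ).drop_duplicates("sseqid")
        out[str(query)] = set(by_bits["sseqid"].head(k)) | set(
            by_ident["sseqid"].head(k)
        )
    return out


# ---------------------------------------------------------------------------
# Monophyly-based ortholog validation
# ---------------------------------------------------------------------------

def validate_orthologs(
    gene_tree: RootedTree,
    reference: str,
    candidates,
    eligible=None,
) -> set[str]:
    """Candidates monophyletic with the reference, excluding other homologs.

    Finds the largest clade containing ``reference`` whose leaves all lie
    in ``{reference} | eligible`` (by default the candidate set itself;
    pass the full set of red-algal labels to tolerate non-candidate red
    sequences inside the clade) and returns the candidates inside it.
    """
    labels = gene_tree.label_set()
    if reference not in labels:
        raise TreeError(f"reference {reference!r} absent from gene tree")
    candidates = set(candidates)
    allowed = {reference} | (set(eligible) if eligible is not None else candidates)
    sets = gene_tree._node_leafsets()
    best: frozenset[str] = frozenset([reference])
    for node in gene_tree.postorder():
        s = sets[node]
        if reference in s and s <= allowed and len(s) > len(best):
            best = s
    return candidates & best


# ---------------------------------------------------------------------------
# Presence matrix
# ---------------------------------------------------------------------------

@dataclass
class PresenceMatrix:
    """Gene (enzyme) x taxon states with optional pathway membership labels."""

    frame: pd.DataFrame  # index = genes, columns = taxa, values = states
    pathways: dict[str, tuple[str, ...]] = field(default_factory=dict)

    def __post_init__(self):
        bad = set(self.frame.values.ravel()) - {PRESENT, ABSENT, AMBIGUOUS}
        if bad:
            raise ValueError(f"illegal states: {sorted(bad)}")

    def character(self, gene: str) -> dict[str, str]:
        return dict(self.frame.loc[gene])

    def write_tsv(self, path) -> None:
        coded = self.frame.map(lambda s: _STATE_CODE[s])
        coded.to_csv(path, sep="\t", index_label="gene")

    @classmethod
    def read_tsv(cls, path) -> "PresenceMatrix":
        coded = pd.read_csv(path, sep="\t", index_col="gene", dtype=str)
        return cls(coded.map(lambda c: _CODE_STATE[c]))


def call_presence(
    validated: dict[str, dict[str, set[str]]],
    taxa: TaxonTable,
    transcriptome_absence: str = AMBIGUOUS,
) -> PresenceMatrix:
    """State calls from validated ortholog sets, per gene per taxon.

    ``validated[gene][taxon]`` holds that taxon's validated orthologs for
    the gene.  A taxon with at least one ortholog is 'present'; otherwise
    genome/partial-genome taxa are 'absent' and transcriptome taxa get the
    ``transcriptome_absence`` policy state ('ambiguous' by default;
    'absent' when transcriptome absences are independently supported).
    """
    if transcriptome_absence not in (ABSENT, AMBIGUOUS):
        raise ValueError("transcriptome_absence must be 'absent' or 'ambiguous'")
    taxon_ids = list(taxa.frame["taxon_id"])
    rows = {}
    for gene, per_taxon in validated.items():
        states = {}
        for t in taxon_ids:
            if per_taxon.get(t):
                states[t] = PRESENT
            else:
                dtype = taxa.data_type_of(t)
                states[t] = (
                    transcriptome_absence if dtype == "transcriptome" else ABSENT
                )
        rows[gene] = states
    frame = pd.DataFrame.from_dict(rows, orient="index")[taxon_ids]
    return PresenceMatrix(frame)


def pathway_present(
    states: dict[str, str], core_enzymes, min_fraction: float = 0.5
) -> bool:
    """Pathway-level call: present iff >= ceil(min_fraction * len(core))
    of the designated core enzymes are present."""
    import math

    core = list(core_enzymes)
    need = math.ceil(len(core) * min_fraction)
    return sum(states.get(e) == PRESENT for e in core) >= need


# ---------------------------------------------------------------------------
# Dollo parsimony loss mapping
# ---------------------------------------------------------------------------

@dataclass
class LossMap:
    """Single-gain Dollo reconstruction of one presence/absence character."""

    gain_clade: frozenset[str]
    loss_clades: list[frozenset[str]]

    @property
    def loss_count(self) -> int:
        return len(self.loss_clades)


def dollo_losses(
    species_tree: RootedTree,
    character: dict[str, str],
    force_root_gain: bool = False,
) -> LossMap:
    """Minimal Dollo loss mapping of one character onto the species tree.

    The single gain sits at the MRCA of all present leaves (or at the root
    when ``force_root_gain``, for characters presumed ancestral).  Losses
    are the maximal subtrees inside the gain clade containing no present
    leaf and at least one strictly absent leaf; ambiguous leaves never
    force a loss but may be absorbed into one.
    """
    labels = species_tree.label_set()
    missing = labels - set(character)
    if missing:
        raise TreeError(f"character undefined for leaves: {sorted(missing)}")
    bad = {s for s in character.values()} - {PRESENT, ABSENT, AMBIGUOUS}
    if bad:
        raise ValueError(f"illegal states: {sorted(bad)}")
    present = {l for l in labels if character[l] == PRESENT}
    if not present:
        raise TreeError("character has no present leaf; no gain to place")

    gain = species_tree.root if force_root_gain else species_tree.mrca(present)
    sets = species_tree._node_leafsets()

    losses: list[frozenset[str]] = []

    def visit(node) -> None:
        s = sets[node]
        has_present = any(character[l] == PRESENT for l in s)
        if not has_present:
            if any(character[l] == ABSENT for l in s):
                losses.append(s)
            return
        for child in node.children:
            visit(child)

    for child in gain.children:
        visit(child)
    losses.sort(key=lambda s: sorted(s)[0])
    return LossMap(gain_clade=sets[gain], loss_clades=losses)


def loss_report(loss_maps: dict[str, LossMap]) -> pd.DataFrame:
    """Tabular loss report: one row per character."""
    rows = []
    for char, lm in loss_maps.items():
        rows.append(
            {
                "character": char,
                "gain_clade": ",".join(sorted(lm.gain_clade)),
                "loss_clades": ";".join(
                    ",".join(sorted(c)) for c in lm.loss_clades
                ),
                "loss_count": lm.loss_count,
            }
        )
    return pd.DataFrame(rows, columns=["character", "gain_clade", "loss_clades", "loss_count"])
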