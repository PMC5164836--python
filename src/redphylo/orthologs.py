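"""Single-copy orthologous gene-family selection.

Consumes OrthoMCL-style ``groups.txt`` clusters and per-gene protein
alignments, and applies the copy-number, missingness and alignment-size
retention criteria: one gene copy per species, missing data tolerated in
up to three red algae and at most one green alga, and trimmed alignments
kept only when longer than 150 amino acids with at least 15 sequences.
Outgroup representation is reduced to a single green alga by a fixed
priority order.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

AMINO_ACIDS = tuple("ACDEFGHIKLMNPQRSTVWY")
_ALLOWED = set(AMINO_ACIDS) | {"-", "X"}

DEFAULT_OUTGROUP_PRIORITY = (
    "Chlamydomonas_reinhardtii",
    "Chlorella_variabilis",
    "Micromonas_pusilla",
)


class FormatError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Taxon table
# ---------------------------------------------------------------------------

@dataclass
class TaxonTable:
    """The study's taxon panel: id, display name, red/green lineage group,
    ecological class label and data type (genome / partial genome /
    transcriptome)."""

    frame: pd.DataFrame

    REQUIRED = ("taxon_id", "name", "group", "class", "data_type")

    def __post_init__(self):
        missing = set(self.REQUIRED) - set(self.frame.columns)
        if missing:
            raise FormatError(f"taxon table missing columns: {sorted(missing)}")
        if self.frame["taxon_id"].duplicated().any():
            dupes = self.frame.loc[self.frame["taxon_id"].duplicated(), "taxon_id"]
            raise FormatError(f"duplicate taxon ids: {sorted(dupes)}")
        bad = set(self.frame["group"]) - {"red", "green"}
        if bad:
            raise FormatError(f"unknown lineage groups: {sorted(bad)}")
        self._group = dict(zip(self.frame["taxon_id"], self.frame["group"]))
        self._dtype = dict(zip(self.frame["taxon_id"], self.frame["data_type"]))
        self._class = dict(zip(self.frame["taxon_id"], self.frame["class"]))

    @classmethod
    def read_tsv(cls, path) -> "TaxonTable":
        return cls(pd.read_csv(path, sep="\t", dtype=str))

    def write_tsv(self, path) -> None:
        self.frame.to_csv(path, sep="\t", index=False)

    def __contains__(self, taxon_id: str) -> bool:
        return taxon_id in self._group

    def red_taxa(self) -> list[str]:
        return list(self.frame.loc[self.frame["group"] == "red", "taxon_id"])

    def green_taxa(self) -> list[str]:
        return list(self.frame.loc[self.frame["group"] == "green", "taxon_id"])

    def group_of(self, taxon_id: str) -> str:
        return self._group[taxon_id]

    def data_type_of(self, taxon_id: str) -> str:
        return self._dtype[taxon_id]

    def class_of(self, taxon_id: str) -> str:
        return self._class[taxon_id]


# ---------------------------------------------------------------------------
# Orthogroups
# ---------------------------------------------------------------------------

class OrthoGroupSet:
    """Clusters of (taxon, gene) members keyed by group id."""

    def __init__(self, groups: dict[str, list[tuple[str, str]]]):
        self.groups = groups
        for gid, members in groups.items():
            genes = [g for _, g in members]
            if len(set(genes)) != len(genes):
                raise FormatError(f"duplicate gene ids within group {gid}")

    def __len__(self) -> int:
        return len(self.groups)

    def __iter__(self):
        return iter(self.groups.items())

    def __getitem__(self, gid: str) -> list[tuple[str, str]]:
        return self.groups[gid]

    def taxa_of(self, gid: str) -> list[str]:
        return [t for t, _ in self.groups[gid]]

    def write(self, path) -> None:
        with open(path, "w") as fh:
            for gid, members in self.groups.items():
                body = " ".join(f"{t}|{g}" for t, g in members)
                fh.write(f"{gid}: {body}\n")


def parse_groups(source, taxa: TaxonTable | None = None) -> OrthoGroupSet:
    """Parse an OrthoMCL-style groups file: ``GROUPID: taxA|g1 taxB|g2 ...``.

    ``source`` is a path or open text handle.  Raises with the offending
    line number on malformed lines, and names any member taxon absent from
    ``taxa`` when a taxon table is supplied.
    """
    close = False
    if isinstance(source, (str, bytes)) or hasattr(source, "__fspath__"):
        fh = open(source)
        close = True
    else:
        fh = source
    groups: dict[str, list[tuple[str, str]]] = {}
    try:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if ":" not in line:
                raise FormatError(f"line {lineno}: missing ':' group separator")
            gid, _, body = line.partition(":")
            gid = gid.strip()
            if not gid:
                raise FormatError(f"line {lineno}: empty group id")
            if gid in groups:
                raise FormatError(f"line {lineno}: duplicate group id {gid}")
            members = []
            for tok in body.split():
                if "|" not in tok:
                    raise FormatError(
                        f"line {lineno}: member {tok!r} lacks 'taxon|gene' form"
                    )
                taxon, _, gene = tok.partition("|")
                if taxa is not None and taxon not in taxa:
                    raise FormatError(f"line {lineno}: unknown taxon {taxon!r}")
                members.append((taxon, gene))
            groups[gid] = members
    finally:
        if close:
            fh.close()
    return OrthoGroupSet(groups)


# ---------------------------------------------------------------------------
# Gene alignments
# ---------------------------------------------------------------------------

@dataclass
class GeneAlignment:
    """One gene's aligned amino-acid rows, ids conventionally "taxon|gene"."""

    gene_id: str
    rows: list[tuple[str, str]]

    def __post_init__(self):
        lengths = {len(s) for _, s in self.rows}
        if len(lengths) > 1:
            raise FormatError(
                f"alignment {self.gene_id} is ragged (row lengths {sorted(lengths)})"
            )
        for rid, seq in self.rows:
            bad = set(seq.upper()) - _ALLOWED
            if bad:
                raise FormatError(
                    f"alignment {self.gene_id}, row {rid}: illegal characters {sorted(bad)}"
                )

    @property
    def n_columns(self) -> int:
        return len(self.rows[0][1]) if self.rows else 0

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    def taxa(self) -> list[str]:
        return [rid.partition("|")[0] for rid, _ in self.rows]

    @classmethod
    def from_fasta(cls, path, gene_id: str | None = None) -> "GeneAlignment":
        records = list(SeqIO.parse(path, "fasta"))
        gid = gene_id or str(getattr(path, "name", path))
        return cls(gid, [(r.id, str(r.seq)) for r in records])

    def to_fasta(self, path) -> None:
        records = [
            SeqRecord(Seq(seq), id=rid, description="") for rid, seq in self.rows
        ]
        SeqIO.write(records, path, "fasta")

    def relabel_to_taxa(self) -> "GeneAlignment":
        """Replace row ids by their taxon prefix (requires one row per taxon)."""
        taxa = self.taxa()
        if len(set(taxa)) != len(taxa):
            raise FormatError(f"alignment {self.gene_id} has repeated taxa")
        return GeneAlignment(
            self.gene_id, [(t, seq) for t, (_, seq) in zip(taxa, self.rows)]
        )


# ---------------------------------------------------------------------------
# Filters
# ---------------------------------------------------------------------------

REJECTION_ORDER = ("multi-copy", "red-missingness", "green-missingness")


def select_single_copy(
    groups: OrthoGroupSet,
    taxa: TaxonTable,
    max_missing_red: int = 3,
    max_missing_green: int = 1,
) -> tuple[list[str], pd.DataFrame]:
    """Single-copy selection with bounded missingness.

    A group passes iff no taxon contributes two or more members, at most
    ``max_missing_red`` red taxa are absent and at most ``max_missing_green``
    green taxa are absent.  Returns the retained group ids plus a rejection
    table recording, per failed group, the first violated criterion in the
    fixed order multi-copy -> red-missingness -> green-missingness.
    """
    red = set(taxa.red_taxa())
    green = set(taxa.green_taxa())
    retained: list[str] = []
    rejected: list[dict] = []
    for gid, members in groups:
        mtaxa = [t for t, _ in members]
        unknown = set(mtaxa) - red - green
        if unknown:
            raise FormatError(
                f"group {gid}: member taxa not in taxon table: {sorted(unknown)}"
            )
        present = set(mtaxa)
        reason = None
        if len(mtaxa) != len(present):
            reason = "multi-copy"
        elif len(red - present) > max_missing_red:
            reason = "red-missingness"
        elif len(green - present) > max_missing_green:
            reason = "green-missingness"
        if reason is None:
            retained.append(gid)
        else:
            rejected.append({"group_id": gid, "reason": reason})
    report = pd.DataFrame(rejected, columns=["group_id", "reason"])
    return retained, report


def filter_alignments(
    alignments,
    min_length_exclusive: int = 150,
    min_sequences: int = 15,
) -> list[GeneAlignment]:
    """Retain alignments longer than ``min_length_exclusive`` columns
    (strict) with at least ``min_sequences`` rows."""
    return [
        a
        for a in alignments
        if a.n_columns > min_length_exclusive and a.n_rows >= min_sequences
    ]


def reduce_outgroup(
    alignment: GeneAlignment,
    priority=DEFAULT_OUTGROUP_PRIORITY,
) -> GeneAlignment:
    """Keep only the highest-priority green (outgroup) row.

    ``priority`` is the ordered list of green taxa; rows of other taxa are
    untouched.  If no green row is present the alignment is returned
    unchanged with a warning.
    """
    priority = list(priority)
    green_rows = [
        (rid, seq) for rid, seq in alignment.rows if rid.partition("|")[0] in priority
    ]
    if not green_rows:
        warnings.warn(
            f"alignment {alignment.gene_id}: no outgroup row present", stacklevel=2
        )
        return alignment
    rank = {t: i for i, t in enumerate(priority)}
    keep_id = min(green_rows, key=lambda r: rank[r[0].partition("|")[0]])[0]
    rows = [
        (rid, seq)
        for rid, seq in alignment.rows
        if rid.partition("|")[0] not in rank or rid == keep_id
    ]
    return GeneAlignment(alignment.gene_id, rows)


def prefilter_short_sequences(
    sequences: dict[str, str], min_length: int = 100
) -> dict[str, str]:
    """Optional upstream pre-filter dropping sequences shorter than 100 aa
    (gap characters not counted)."""
    return {
        k: v
        for k, v in sequences.items()
        if len(v.replace("-", "")) >= min_length
    }


def trim_gap_columns(alignment: GeneAlignment, max_gap_fraction: float = 0.5) -> GeneAlignment:
    """Plumbing-only gap trimmer: drop columns with > ``max_gap_fraction`` gaps.

    A deliberately simple stand-in for dedicated alignment-trimming tools;
    not equivalent to conservation-score trimming.
    """
    if not alignment.rows:
        return alignment
    n = alignment.n_rows
    keep = [
        c
        for c in range(alignment.n_columns)
        if sum(1 for _, s in alignment.rows if s[c] == "-") <= max_gap_fraction * n
    ]
    rows = [(rid, "".join(seq[c] for c in keep)) for rid, seq in alignment.rows]
    return GeneAlignment(alignment.gene_id, rows)
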