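"""Concatenation of per-gene alignments into a partitioned supermatrix.

Taxa absent from a gene receive all-gap blocks; partitions are recorded
with 1-based inclusive coordinates and exported in the RAxML dialect.
The supermatrix is an export product for external concatenation
analyses; no tree inference happens here.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .orthologs import FormatError, GeneAlignment

GAP = "-"


@dataclass
class Partition:
    gene_id: str
    start: int  # 1-based inclusive
    end: int    # 1-based inclusive

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class Supermatrix:
    taxa: list[str]
    sequences: dict[str, str]
    partitions: list[Partition]

    def __post_init__(self):
        lengths = {len(s) for s in self.sequences.values()}
        if len(lengths) > 1:
            raise FormatError("supermatrix rows have unequal lengths")
        if self.partitions:
            expect = 1
            for p in self.partitions:
                if p.start != expect or p.end < p.start:
                    raise FormatError(
                        f"partitions do not tile the matrix at {p.gene_id}"
                    )
                expect = p.end + 1
            if lengths and expect - 1 != next(iter(lengths)):
                raise FormatError("partitions do not cover the full matrix")

    @property
    def n_columns(self) -> int:
        return len(next(iter(self.sequences.values()))) if self.sequences else 0

    def extract(self, gene_id: str) -> GeneAlignment:
        """Recover one gene's alignment block (taxa with any residue)."""
        part = next(p for p in self.partitions if p.gene_id == gene_id)
        rows = []
        for t in self.taxa:
            block = self.sequences[t][part.start - 1 : part.end]
            if set(block) != {GAP}:
                rows.append((t, block))
        return GeneAlignment(gene_id, rows)


def concatenate(alignments, taxa: list[str] | None = None) -> Supermatrix:
    """Concatenate gene alignments (row ids "taxon|gene" or plain taxa).

    Gene order follows the input; pass alignments sorted by gene id for a
    deterministic matrix.  A taxon missing from a gene gets an all-gap
    block of that gene's length.
    """
    alignments = list(alignments)
    if taxa is None:
        seen: list[str] = []
        for aln in alignments:
            for t in aln.taxa():
                if t not in seen:
                    seen.append(t)
        taxa = sorted(seen)
    chunks: dict[str, list[str]] = {t: [] for t in taxa}
    partitions: list[Partition] = []
    pos = 1
    for aln in alignments:
        rows: dict[str, str] = {}
        for rid, seq in aln.rows:
            t = rid.partition("|")[0]
            if t in rows:
                raise FormatError(
                    f"gene {aln.gene_id}: two rows for taxon {t!r}"
                )
            rows[t] = seq
        width = aln.n_columns
        for t in taxa:
            chunks[t].append(rows.get(t, GAP * width))
        partitions.append(Partition(aln.gene_id, pos, pos + width - 1))
        pos += width
    return Supermatrix(
        taxa=list(taxa),
        sequences={t: "".join(chunks[t]) for t in taxa},
        partitions=partitions,
    )


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def write_fasta(sm: Supermatrix, path) -> None:
    records = [
        SeqRecord(Seq(sm.sequences[t]), id=t, description="") for t in sm.taxa
    ]
    SeqIO.write(records, path, "fasta")


def read_fasta(path) -> Supermatrix:
    """Read a supermatrix FASTA (partition structure not recoverable)."""
    records = list(SeqIO.parse(path, "fasta"))
    taxa = [r.id for r in records]
    return Supermatrix(
        taxa=taxa,
        sequences={r.id: str(r.seq) for r in records},
        partitions=[],
    )


def write_phylip(sm: Supermatrix, path) -> None:
    """Relaxed PHYLIP: '<ntaxa> <ncols>' header, 'name  sequence' rows."""
    for t in sm.taxa:
        if any(ch.isspace() for ch in t):
            raise FormatError(f"taxon name contains whitespace: {t!r}")
    with open(path, "w") as fh:
        fh.write(f"{len(sm.taxa)} {sm.n_columns}\n")
        for t in sm.taxa:
            fh.write(f"{t}  {sm.sequences[t]}\n")


def write_partitions(sm: Supermatrix, path) -> None:
    """RAxML-style partition file: 'PROT, <gene> = <start>-<end>'."""
    with open(path, "w") as fh:
        for p in sm.partitions:
            fh.write(f"PROT, {p.gene_id} = {p.start}-{p.end}\n")
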