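"""Gene-structure container and annotation I/O.

All coordinates are held internally as 0-based, half-open intervals on the
genome-forward strand; GTF input/output converts to and from the 1-based,
closed convention that format requires. Sequences are plain upper-case
strings keyed by contig name.
"""

from __future__ import annotations

import tempfile
from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq

__all__ = [
    "TranscriptModel",
    "read_fasta",
    "write_fasta",
    "read_gtf",
    "write_gtf",
    "reverse_complement",
]


def reverse_complement(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


@dataclass
class TranscriptModel:
    """A single-transcript gene model.

    exons are non-overlapping [start, end) intervals sorted in ascending
    genomic order regardless of strand; introns are the gaps between
    consecutive exons.
    """

    gene_id: str
    transcript_id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if not self.exons:
            raise ValueError(f"{self.gene_id}: transcript needs at least one exon")
        ex = sorted(self.exons)
        for (s1, e1), (s2, e2) in zip(ex, ex[1:]):
            if s2 < e1:
                raise ValueError(f"{self.gene_id}: overlapping exons {(s1, e1)} / {(s2, e2)}")
        for s, e in ex:
            if not (0 <= s < e):
                raise ValueError(f"{self.gene_id}: bad exon interval {(s, e)}")
        self.exons = ex

    @property
    def introns(self) -> list[tuple[int, int]]:
        """Gaps between consecutive exons, genome-forward order."""
        return [(e1, s2) for (_, e1), (s2, _) in zip(self.exons, self.exons[1:])]

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    def n_introns(self) -> int:
        return len(self.exons) - 1

    # -- sequence extraction -------------------------------------------------

    def exon_seqs_fwd(self, genome: dict[str, str]) -> list[str]:
        contig = genome[self.chrom]
        return [contig[s:e] for s, e in self.exons]

    def intron_seqs_fwd(self, genome: dict[str, str]) -> list[str]:
        contig = genome[self.chrom]
        return [contig[s:e] for s, e in self.introns]

    def spliced_mrna(self, genome: dict[str, str]) -> str:
        """Mature mRNA in transcript orientation (5'→3')."""
        seq = "".join(self.exon_seqs_fwd(genome))
        return seq if self.strand == "+" else reverse_complement(seq)

    def retained_mrna(self, genome: dict[str, str], intron_index: int) -> str:
        """mRNA with one intron retained, transcript orientation.

        intron_index counts introns in transcript (5'→3') order.
        """
        gi = self._genomic_intron_index(intron_index)
        contig = genome[self.chrom]
        parts: list[str] = []
        for i, (s, e) in enumerate(self.exons):
            parts.append(contig[s:e])
            if i == gi:
                istart, iend = self.introns[gi]
                parts.append(contig[istart:iend])
        seq = "".join(parts)
        return seq if self.strand == "+" else reverse_complement(seq)

    def _genomic_intron_index(self, intron_index: int) -> int:
        n = self.n_introns()
        if not 0 <= intron_index < n:
            raise IndexError(
                f"{self.gene_id}: intron index {intron_index} out of range (0..{n - 1})"
            )
        return intron_index if self.strand == "+" else n - 1 - intron_index

    def intron_tx_offset(self, genome: dict[str, str], intron_index: int) -> int:
        """Transcript-coordinate start of a retained intron (5'→3' numbering)."""
        gi = self._genomic_intron_index(intron_index)
        exon_lens = [e - s for s, e in self.exons]
        if self.strand == "+":
            return sum(exon_lens[: gi + 1])
        return sum(exon_lens[gi + 1 :])


# -- FASTA ------------------------------------------------------------------


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(genome: dict[str, str], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name in genome:
            fh.write(f">{name}\n")
            seq = genome[name]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# -- GTF --------------------------------------------------------------------


def write_gtf(transcripts: list[TranscriptModel], path: str | Path) -> None:
    """1-based closed intervals, gene_id/transcript_id attributes."""
    with open(path, "w") as fh:
        for t in transcripts:
            attrs = f'gene_id "{t.gene_id}"; transcript_id "{t.transcript_id}";'
            fh.write(
                "\t".join(
                    [t.chrom, "spliceometab", "transcript", str(t.start + 1),
                     str(t.end), ".", t.strand, ".", attrs]
                )
                + "\n"
            )
            for s, e in t.exons:
                fh.write(
                    "\t".join(
                        [t.chrom, "spliceometab", "exon", str(s + 1), str(e),
                         ".", t.strand, ".", attrs]
                    )
                    + "\n"
                )


def read_gtf(path: str | Path) -> list[TranscriptModel]:
    """Parse a GTF into transcript models (gffutils, in-memory db)."""
    import gffutils

    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="merge",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    out: list[TranscriptModel] = []
    for tx in db.features_of_type("transcript"):
        exons = [
            (ex.start - 1, ex.end)
            for ex in db.children(tx, featuretype="exon", order_by="start")
        ]
        out.append(
            TranscriptModel(
                gene_id=tx.attributes["gene_id"][0],
                transcript_id=tx.attributes["transcript_id"][0],
                chrom=tx.seqid,
                strand=tx.strand,
                exons=exons,
            )
        )
    out.sort(key=lambda t: t.transcript_id)
    return out
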