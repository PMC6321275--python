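"""Reading, writing and filtering of reads and reference transcripts.

All sequences are normalized to uppercase RNA ({A, C, G, U}) at parse time;
every downstream module assumes that alphabet.  Reads are plain FASTQ
(Sanger Phred+33); transcripts are FASTA plus a TSV sidecar carrying gene ID,
gene class and a genomic interval (0-based half-open) with strand.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

RNA_ALPHABET = frozenset("ACGU")

GENE_CLASSES = (
    "rRNA",
    "mRNA",
    "tRNA",
    "lincRNA",
    "antisense",
    "pseudogene",
    "other",
)

_COMPLEMENT = str.maketrans("ACGU", "UGCA")


def normalize_rna(seq: str) -> str:
    """Uppercase and convert DNA T to RNA U."""
    return seq.upper().replace("T", "U")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def gc_fraction(seq: str) -> float:
    """Fraction of G+C over sequence length (0 for empty input)."""
    if not seq:
        return 0.0
    return sum(1 for c in seq if c in "GC") / len(seq)


class FastqParseError(ValueError):
    """Raised for malformed FASTQ records; carries the record index."""

    def __init__(self, index: int, message: str):
        self.index = index
        super().__init__(f"record {index}: {message}")


@dataclass(frozen=True)
class ReadRecord:
    """One sequencing read: ID, RNA sequence and per-base Phred qualities.

    ``quals`` is None for FASTA-derived fixtures that carry no qualities.
    """

    read_id: str
    seq: str
    quals: tuple[int, ...] | None = None

    def __post_init__(self):
        if self.quals is not None and len(self.quals) != len(self.seq):
            raise ValueError(
                f"read {self.read_id}: {len(self.quals)} qualities for "
                f"{len(self.seq)} bases"
            )
        bad = set(self.seq) - RNA_ALPHABET
        if bad:
            raise ValueError(f"read {self.read_id}: non-RNA symbols {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class Transcript:
    """Reference RNA with gene-level annotation and a genomic interval.

    ``interval`` is (chrom, start, end, strand), 0-based half-open,
    strand in {+, -}.
    """

    transcript_id: str
    gene_id: str
    gene_class: str
    seq: str
    interval: tuple[str, int, int, str]

    def __post_init__(self):
        chrom, start, end, strand = self.interval
        if not self.seq:
            raise ValueError(f"transcript {self.transcript_id}: empty sequence")
        if start >= end:
            raise ValueError(
                f"transcript {self.transcript_id}: interval start {start} >= end {end}"
            )
        if strand not in ("+", "-"):
            raise ValueError(f"transcript {self.transcript_id}: bad strand {strand!r}")

    def __len__(self) -> int:
        return len(self.seq)


def read_fastq(path: str | Path) -> list[ReadRecord]:
    """Parse a Sanger-encoded FASTQ file into ReadRecords (T converted to U).

    Raises FastqParseError naming the 0-based record index on malformed
    records (e.g. quality string shorter than the sequence).
    """
    reads: list[ReadRecord] = []
    with open(path) as handle:
        for index, rec in enumerate(_iter_fastq(handle)):
            rid, seq, quals = rec
            try:
                reads.append(ReadRecord(rid, normalize_rna(seq), tuple(quals)))
            except ValueError as exc:
                raise FastqParseError(index, str(exc)) from exc
    return reads


def _iter_fastq(handle):
    # Biopython's FastqGeneralIterator validates the 4-line structure and
    # seq/qual length agreement; re-raise its errors with a record index.
    from Bio.SeqIO.QualityIO import FastqGeneralIterator

    index = 0
    iterator = FastqGeneralIterator(handle)
    while True:
        try:
            title, seq, qual = next(iterator)
        except StopIteration:
            return
        except ValueError as exc:
            raise FastqParseError(index, str(exc)) from exc
        yield title.split()[0], seq, [ord(c) - 33 for c in qual]
        index += 1


def write_fastq(reads: Iterable[ReadRecord], path: str | Path) -> None:
    """Write reads as Sanger FASTQ; reads lacking qualities get Phred 40."""
    with open(path, "w") as handle:
        for read in reads:
            quals = read.quals if read.quals is not None else (40,) * len(read)
            handle.write(f"@{read.read_id}\n{read.seq}\n+\n")
            handle.write("".join(chr(q + 33) for q in quals) + "\n")


def read_transcripts(fasta_path: str | Path, annotation_path: str | Path) -> list[Transcript]:
    """Load transcripts from FASTA plus a TSV annotation sidecar.

    The sidecar has columns transcript_id, gene_id, gene_class, chrom,
    start, end, strand.  Every FASTA record must be annotated.
    """
    ann = pd.read_csv(annotation_path, sep="\t", dtype={"chrom": str})
    ann = ann.set_index("transcript_id")
    transcripts = []
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        if rec.id not in ann.index:
            raise KeyError(f"transcript {rec.id} missing from annotation table")
        row = ann.loc[rec.id]
        transcripts.append(
            Transcript(
                transcript_id=rec.id,
                gene_id=str(row["gene_id"]),
                gene_class=str(row["gene_class"]),
                seq=normalize_rna(str(rec.seq)),
                interval=(str(row["chrom"]), int(row["start"]), int(row["end"]), str(row["strand"])),
            )
        )
    return transcripts


def write_transcripts(
    transcripts: Sequence[Transcript],
    fasta_path: str | Path,
    annotation_path: str | Path,
) -> None:
    records = [
        SeqRecord(Seq(t.seq), id=t.transcript_id, description="")
        for t in transcripts
    ]
    SeqIO.write(records, str(fasta_path), "fasta")
    rows = [
        {
            "transcript_id": t.transcript_id,
            "gene_id": t.gene_id,
            "gene_class": t.gene_class,
            "chrom": t.interval[0],
            "start": t.interval[1],
            "end": t.interval[2],
            "strand": t.interval[3],
        }
        for t in transcripts
    ]
    pd.DataFrame(rows).to_csv(annotation_path, sep="\t", index=False)


def quality_trim(read: ReadRecord, window: int = 10, qmin: int = 20) -> ReadRecord | None:
    """3'-trim at the first sliding window whose mean quality drops below qmin.

    Windows slide 5'->3' one base at a time; at the first window whose mean
    quality falls below qmin, the read is cut at the first sub-qmin base
    inside that window (a mean below qmin guarantees one exists).  Returns
    None when nothing survives.  Reads without qualities pass through
    untouched.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    if read.quals is None:
        return read
    quals = read.quals
    n = len(quals)
    cut = n
    for p in range(0, max(n - window + 1, 1)):
        w = quals[p : p + window]
        if sum(w) / len(w) < qmin:
            cut = p + next(off for off, q in enumerate(w) if q < qmin)
            break
    if cut == 0:
        return None
    if cut == n:
        return read
    return ReadRecord(read.read_id, read.seq[:cut], quals[:cut])


def length_filter(reads: Sequence[ReadRecord], min_exclusive: int = 18) -> list[ReadRecord]:
    """Keep reads strictly longer than ``min_exclusive`` nt, preserving order.

    The protocol's size cut keeps only fragments longer than 18 nt, so the
    boundary value itself is excluded.
    """
    return [r for r in reads if len(r) > min_exclusive]
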