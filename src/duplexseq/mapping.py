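"""Perfect-identity read-to-transcript matching and coverage enrichment.

Reads are matched to transcripts by full-length exact substring occurrence
on the forward strand only (antisense relationships are handled at the
genomic-interval level in :mod:`duplexseq.antisense`).  A read matching k
locations across the transcriptome contributes weight 1/k to each, so
every mapped read carries total weight 1.  Coverage is per-nucleotide
weighted counts, summarized through a three-level averaging hierarchy:
position mean per transcript, transcript mean per gene, gene mean per
class; the ratio of per-class averages between two treatments is the class
enrichment.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .seqio import ReadRecord, Transcript


@dataclass(frozen=True)
class Match:
    """One full-length exact occurrence of a read in a transcript.

    Transcript coordinates are 0-based half-open; ``weight`` is 1/k with k
    the total number of occurrences of the read across the transcriptome.
    """

    read_id: str
    transcript_id: str
    t_start: int
    t_end: int
    weight: float


@dataclass
class CoverageProfile:
    """Per-position weighted read counts along one transcript."""

    transcript_id: str
    cov: np.ndarray

    def mean(self) -> float:
        return float(self.cov.mean())


class TranscriptIndex:
    """Exact substring lookup over a transcript set (forward strand).

    A plain scan with ``str.find`` per transcript; transcript order does
    not affect results because all occurrences are always enumerated.
    """

    def __init__(self, transcripts: Sequence[Transcript]):
        self.transcripts = list(transcripts)
        self.by_id = {t.transcript_id: t for t in self.transcripts}
        if len(self.by_id) != len(self.transcripts):
            raise ValueError("duplicate transcript IDs")

    def occurrences(self, seq: str) -> list[tuple[str, int]]:
        """All (transcript_id, start) occurrences, sorted by (id, start)."""
        hits = []
        for t in self.transcripts:
            start = t.seq.find(seq)
            while start != -1:
                hits.append((t.transcript_id, start))
                start = t.seq.find(seq, start + 1)
        return sorted(hits)


def map_read(read: ReadRecord, index: TranscriptIndex) -> list[Match]:
    """All full-length exact matches of the read, multi-match corrected.

    Returns an empty list for unmatched reads.
    """
    hits = index.occurrences(read.seq)
    if not hits:
        return []
    weight = 1.0 / len(hits)
    return [
        Match(read.read_id, tid, start, start + len(read), weight)
        for tid, start in hits
    ]


def map_reads(reads: Iterable[ReadRecord], index: TranscriptIndex) -> list[Match]:
    out: list[Match] = []
    for read in reads:
        out.extend(map_read(read, index))
    return out


def coverage_profiles(
    matches: Iterable[Match], transcripts: Sequence[Transcript]
) -> dict[str, CoverageProfile]:
    """Accumulate match weights into per-transcript coverage arrays.

    Every transcript gets a profile (all-zero when unmatched); matches to
    unknown transcripts or out-of-range coordinates raise.
    """
    profiles = {
        t.transcript_id: CoverageProfile(t.transcript_id, np.zeros(len(t)))
        for t in transcripts
    }
    for m in matches:
        if m.transcript_id not in profiles:
            raise KeyError(f"match to unknown transcript {m.transcript_id}")
        cov = profiles[m.transcript_id].cov
        if m.t_start < 0 or m.t_end > cov.size:
            raise ValueError(
                f"match {m.read_id} out of range on {m.transcript_id}: "
                f"[{m.t_start}, {m.t_end}) vs length {cov.size}"
            )
        cov[m.t_start : m.t_end] += m.weight
    return profiles


def normalize_profile(profile: CoverageProfile) -> CoverageProfile:
    """Scale so the highest coverage value is 1.0 (all-zero stays as is)."""
    peak = profile.cov.max() if profile.cov.size else 0.0
    if peak == 0.0:
        return profile
    return CoverageProfile(profile.transcript_id, profile.cov / peak)


def gene_class_coverage(
    profiles: dict[str, CoverageProfile], transcripts: Sequence[Transcript]
) -> dict[str, float]:
    """Average coverage per gene class via the three-level hierarchy:
    position mean per transcript -> transcript mean per gene -> gene mean
    per class.  Classes with no genes are absent from the output."""
    by_gene: dict[str, list[float]] = defaultdict(list)
    gene_class: dict[str, str] = {}
    for t in transcripts:
        if t.transcript_id in profiles:
            by_gene[t.gene_id].append(profiles[t.transcript_id].mean())
            gene_class[t.gene_id] = t.gene_class
    by_class: dict[str, list[float]] = defaultdict(list)
    for gene, means in by_gene.items():
        by_class[gene_class[gene]].append(float(np.mean(means)))
    return {cls: float(np.mean(v)) for cls, v in sorted(by_class.items())}


def class_enrichment(
    cov_a: dict[str, float], cov_b: dict[str, float]
) -> dict[str, float]:
    """Per-class coverage ratio cov_a / cov_b between two treatments.

    Classes with zero coverage in the denominator map to NaN (flagged
    undefined, never infinite); only shared classes are reported.
    """
    out = {}
    for cls in sorted(set(cov_a) & set(cov_b)):
        denom = cov_b[cls]
        out[cls] = cov_a[cls] / denom if denom != 0 else float("nan")
    return out
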