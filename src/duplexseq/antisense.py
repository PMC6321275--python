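"""Cis-sense/antisense overlap vs read-match contingency analysis.

Per dataset, every gene is tallied into a 2x2 table: does any of its
transcripts' genomic intervals overlap (>= 1 bp, same chromosome) a
transcript of a *different* gene on the opposite strand, and does any read
map to any of its transcripts.  The enrichment factor is the relative risk
(a/(a+b)) / (c/(c+d)) - how much more likely overlap-involved genes are to
carry read matches - aggregated over datasets as mean +/- sample sd.
"""

from __future__ import annotations

import math
import warnings
from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .seqio import Transcript


@dataclass(frozen=True)
class ContingencyTable:
    """Counts over genes: a = overlap & match, b = overlap & no match,
    c = no overlap & match, d = neither."""

    a: int
    b: int
    c: int
    d: int
    dataset_label: str = ""

    def __post_init__(self):
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def n_genes(self) -> int:
        return self.a + self.b + self.c + self.d


def annotate_antisense_overlap(transcripts: Sequence[Transcript]) -> dict[str, bool]:
    """Flag each gene that has a >=1 bp opposite-strand overlap with a
    different gene's transcript on the same chromosome.

    Opposite-strand overlap between transcripts of the same gene does not
    count.  Intervals are 0-based half-open, so abutting intervals do not
    overlap.
    """
    by_chrom: dict[str, list[Transcript]] = defaultdict(list)
    flags: dict[str, bool] = {}
    for t in transcripts:
        if t.interval is None:
            warnings.warn(f"transcript {t.transcript_id} lacks an interval; gene excluded")
            continue
        by_chrom[t.interval[0]].append(t)
        flags.setdefault(t.gene_id, False)
    for chrom, txs in by_chrom.items():
        for i, t1 in enumerate(txs):
            for t2 in txs[i + 1 :]:
                if t1.gene_id == t2.gene_id:
                    continue
                if t1.interval[3] == t2.interval[3]:
                    continue
                if t1.interval[1] < t2.interval[2] and t2.interval[1] < t1.interval[2]:
                    flags[t1.gene_id] = True
                    flags[t2.gene_id] = True
    return flags


def gene_match_flags(
    matches: Iterable, transcripts: Sequence[Transcript]
) -> dict[str, bool]:
    """Per-gene flag: any read maps to any of the gene's transcripts."""
    gene_of = {t.transcript_id: t.gene_id for t in transcripts}
    flags = {t.gene_id: False for t in transcripts}
    for m in matches:
        flags[gene_of[m.transcript_id]] = True
    return flags


def build_contingency(
    overlap_flags: dict[str, bool],
    match_flags: dict[str, bool],
    dataset_label: str = "",
) -> ContingencyTable:
    """Tally the 2x2 table over the shared gene universe.

    The two flag maps must cover exactly the same genes; offenders are
    listed in the error otherwise.
    """
    if set(overlap_flags) != set(match_flags):
        offenders = sorted(set(overlap_flags) ^ set(match_flags))
        raise ValueError(f"gene universes differ; offenders: {offenders}")
    a = b = c = d = 0
    for gene, overlap in overlap_flags.items():
        match = match_flags[gene]
        if overlap and match:
            a += 1
        elif overlap:
            b += 1
        elif match:
            c += 1
        else:
            d += 1
    return ContingencyTable(a, b, c, d, dataset_label)


def enrichment_factor(table: ContingencyTable) -> float:
    """Relative risk of a read match given antisense overlap.

    (a/(a+b)) / (c/(c+d)); NaN (undefined, not infinite) when c == 0.
    Raises on an empty margin.
    """
    if table.a + table.b == 0 or table.c + table.d == 0:
        raise ValueError("empty contingency margin")
    if table.c == 0:
        return math.nan
    risk_overlap = table.a / (table.a + table.b)
    risk_other = table.c / (table.c + table.d)
    return risk_overlap / risk_other


def aggregate_factors(
    tables: Sequence[ContingencyTable],
) -> tuple[float, float, int, int]:
    """Mean and sample sd of per-dataset enrichment factors.

    Undefined (NaN) factors are skipped and counted; at least two defined
    factors are required.  Returns (mean, sd, n_defined, n_undefined).
    """
    factors = [enrichment_factor(t) for t in tables]
    defined = [f for f in factors if not math.isnan(f)]
    n_undef = len(factors) - len(defined)
    if len(defined) < 2:
        raise ValueError("need at least 2 defined enrichment factors")
    arr = np.asarray(defined)
    return float(arr.mean()), float(arr.std(ddof=1)), len(defined), n_undef
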