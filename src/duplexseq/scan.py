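"""All-versus-all duplex scan over reads and longest-helix summaries.

Reads are grouped by exact length; within each group every unordered pair
of distinct reads is scored, and for each read the length (bp) of the
longest contiguous helix found against any partner is recorded.  Two
engines are available: ``max_pairing`` (the longest perfectly
complementary run, fast and string-exact) and ``energy`` (the longest
helix of the minimum-free-energy duplex; the default, matching the use of
an energy-based predictor).  A shuffled control repeats the scan after a
composition-preserving shuffle of every read.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field

import numpy as np

from .duplex import hybrid_mfe, longest_complementary_run
from .energy import DEFAULT_MODEL, EnergyModel
from .nulls import child_seeds, shuffle_sequence
from .seqio import ReadRecord

logger = logging.getLogger(__name__)

ENGINES = ("max_pairing", "energy")


@dataclass
class HelixLengthProfile:
    """Per-read longest helix (bp) against any same-length partner read."""

    per_read_max: dict[str, int]
    best_partner: dict[str, str | None]
    dataset_label: str = ""
    shuffled: bool = False
    n_pairs_scored: int = 0

    def values(self) -> np.ndarray:
        return np.array(list(self.per_read_max.values()), dtype=int)


def planned_pair_count(reads: list[ReadRecord], dedup: bool = True) -> int:
    """Number of pairwise predictions the scan will run: sum of C(|g|, 2)
    over same-length groups (over unique sequences when dedup is on, plus
    one self-comparison per duplicated sequence)."""
    groups = defaultdict(list)
    for r in reads:
        groups[len(r)].append(r.seq)
    total = 0
    for seqs in groups.values():
        if dedup:
            uniq = set(seqs)
            k = len(uniq)
            total += k * (k - 1) // 2
            total += sum(1 for s in uniq if seqs.count(s) > 1)
        else:
            total += len(seqs) * (len(seqs) - 1) // 2
    return total


def _pair_helix_length(seq_a: str, seq_b: str, engine: str, model: EnergyModel) -> int:
    if engine == "max_pairing":
        return longest_complementary_run(seq_a, seq_b)[0]
    if engine == "energy":
        return hybrid_mfe(seq_a, seq_b, model).longest_helix
    raise ValueError(f"unknown engine {engine!r}")


def all_vs_all_scan(
    reads: list[ReadRecord],
    engine: str = "energy",
    dedup: bool = True,
    model: EnergyModel = DEFAULT_MODEL,
    dataset_label: str = "",
) -> HelixLengthProfile:
    """Scan every same-length read pair and record each read's best helix.

    Reads in singleton length groups score 0.  With ``dedup`` (default),
    identical sequences are collapsed to one prediction and the result is
    re-expanded to all carrying read IDs; a sequence present in two or more
    copies is additionally scored against itself, since two identical
    molecules can duplex, while a single read is never paired with its own
    record.  The planned pair count is logged before scanning.
    """
    n_pairs = planned_pair_count(reads, dedup)
    logger.info("all-vs-all scan: %d reads, %d pairwise predictions", len(reads), n_pairs)

    groups: dict[int, list[ReadRecord]] = defaultdict(list)
    for r in reads:
        groups[len(r)].append(r)

    per_read_max = {r.read_id: 0 for r in reads}
    best_partner: dict[str, str | None] = {r.read_id: None for r in reads}

    for length, group in groups.items():
        if len(group) < 2:
            continue
        if dedup:
            by_seq: dict[str, list[str]] = defaultdict(list)
            for r in group:
                by_seq[r.seq].append(r.read_id)
            seqs = list(by_seq)
            for a_idx in range(len(seqs)):
                for b_idx in range(a_idx, len(seqs)):
                    sa, sb = seqs[a_idx], seqs[b_idx]
                    if a_idx == b_idx and len(by_seq[sa]) < 2:
                        continue
                    helix = _pair_helix_length(sa, sb, engine, model)
                    for rid in by_seq[sa]:
                        partner_ids = [x for x in by_seq[sb] if x != rid]
                        if partner_ids and helix > per_read_max[rid]:
                            per_read_max[rid] = helix
                            best_partner[rid] = partner_ids[0]
                    for rid in by_seq[sb]:
                        partner_ids = [x for x in by_seq[sa] if x != rid]
                        if partner_ids and helix > per_read_max[rid]:
                            per_read_max[rid] = helix
                            best_partner[rid] = partner_ids[0]
        else:
            for a_idx in range(len(group)):
                for b_idx in range(a_idx + 1, len(group)):
                    ra, rb = group[a_idx], group[b_idx]
                    helix = _pair_helix_length(ra.seq, rb.seq, engine, model)
                    if helix > per_read_max[ra.read_id]:
                        per_read_max[ra.read_id] = helix
                        best_partner[ra.read_id] = rb.read_id
                    if helix > per_read_max[rb.read_id]:
                        per_read_max[rb.read_id] = helix
                        best_partner[rb.read_id] = ra.read_id

    return HelixLengthProfile(
        per_read_max=per_read_max,
        best_partner=best_partner,
        dataset_label=dataset_label,
        shuffled=False,
        n_pairs_scored=n_pairs,
    )


def scan_summary(profile: HelixLengthProfile) -> tuple[float, int, dict[int, int]]:
    """(median, max, histogram) of the per-read longest-helix lengths.

    Median uses the midpoint convention for even counts; the histogram maps
    helix length -> read count.
    """
    values = profile.values()
    if values.size == 0:
        raise ValueError("empty profile")
    hist = {int(v): int(c) for v, c in zip(*np.unique(values, return_counts=True))}
    return float(np.median(values)), int(values.max()), hist


def shuffled_control_scan(
    reads: list[ReadRecord],
    engine: str = "energy",
    seed: int = 0,
    mode: str = "mono",
    dedup: bool = True,
    model: EnergyModel = DEFAULT_MODEL,
    dataset_label: str = "",
) -> HelixLengthProfile:
    """All-vs-all scan on composition-preserving shuffles of every read.

    Each read gets an independent child seed derived from ``seed``; read
    lengths (hence group sizes) are unchanged.
    """
    seeds = child_seeds(seed, len(reads))
    shuffled_reads = [
        ReadRecord(r.read_id, shuffle_sequence(r.seq, mode, s), r.quals)
        for r, s in zip(reads, seeds)
    ]
    profile = all_vs_all_scan(shuffled_reads, engine, dedup, model, dataset_label)
    profile.shuffled = True
    return profile
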