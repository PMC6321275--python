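"""Detection of chimeric reads: candidate endogenous ligation events.

A chimera call requires the read's 5' end to match one transcript and its
3' end to match a different transcript, both exactly and for at least 18 nt
(inclusive; a distinct threshold from the strict >18 read-length filter),
with non-overlapping read spans.  Reads that match any transcript in their
entirety, or whose two segments both occur on one transcript (an
intra-transcript explanation), are never called.
"""

from __future__ import annotations

from dataclasses import dataclass

from .mapping import TranscriptIndex
from .seqio import ReadRecord


@dataclass(frozen=True)
class ChimeraCall:
    """A read split between two transcripts.

    ``five_prime``/``three_prime`` are (transcript_id, t_start, t_end) for
    the matched segment; the 5' segment covers read span [0, L5) and the 3'
    segment covers [len - L3, len).  ``gap`` is the number of unmatched
    nucleotides between the two segments; ``ambiguous`` marks calls where
    several transcripts tied for either segment.
    """

    read_id: str
    five_prime: tuple[str, int, int]
    three_prime: tuple[str, int, int]
    l5: int
    l3: int
    gap: int
    ambiguous: bool = False


def _longest_prefix_hits(seq: str, index: TranscriptIndex) -> tuple[int, list[tuple[str, int]]]:
    """Longest prefix of ``seq`` occurring anywhere in the index, with all
    its occurrence sites.  Substring presence is monotone in prefix length,
    so binary search applies."""
    lo, hi = 0, len(seq)  # invariant: prefix of length lo occurs, hi+1 does not
    if not index.occurrences(seq[:1]):
        return 0, []
    lo = 1
    while lo < hi:
        mid = (lo + hi + 1) // 2
        if index.occurrences(seq[:mid]):
            lo = mid
        else:
            hi = mid - 1
    return lo, index.occurrences(seq[:lo])


def _longest_suffix_hits(seq: str, index: TranscriptIndex) -> tuple[int, list[tuple[str, int]]]:
    lo, hi = 0, len(seq)
    if not index.occurrences(seq[-1:]):
        return 0, []
    lo = 1
    while lo < hi:
        mid = (lo + hi + 1) // 2
        if index.occurrences(seq[-mid:]):
            lo = mid
        else:
            hi = mid - 1
    return lo, index.occurrences(seq[-lo:])


def find_chimeras(
    reads: list[ReadRecord],
    index: TranscriptIndex,
    min_match: int = 18,
) -> list[ChimeraCall]:
    """Scan reads for 5'/3' split matches onto two different transcripts.

    For each read the longest exact prefix and suffix matches into the
    transcript set are located; a call is emitted only when both reach
    ``min_match``, the read spans do not overlap, the read has no
    full-length match anywhere, and no single transcript carries both
    segments.  When the two maximal segments overlap on the read (chance
    extension into the junction), they are trimmed back - 5' segment
    first - as long as both stay at or above ``min_match``; otherwise no
    call.  When several transcripts tie for a segment, every
    cross-transcript combination is reported and flagged ambiguous.
    """
    calls: list[ChimeraCall] = []
    for read in reads:
        n = len(read)
        if index.occurrences(read.seq):
            continue  # fully explained by one transcript
        l5, hits5 = _longest_prefix_hits(read.seq, index)
        if l5 < min_match:
            continue
        l3, hits3 = _longest_suffix_hits(read.seq, index)
        if l3 < min_match:
            continue
        if l5 + l3 > n:
            # resolve the overlap by trimming, 5' side first
            l5 = max(min_match, n - l3)
            if l5 + l3 > n:
                l3 = max(min_match, n - l5)
            if l5 + l3 > n:
                continue  # both segments already at the floor
            hits5 = index.occurrences(read.seq[:l5])
            hits3 = index.occurrences(read.seq[n - l3 :])
        tx5_set = {tid for tid, _ in hits5}
        tx3_set = {tid for tid, _ in hits3}
        # intra-transcript exclusion: one transcript explains both segments
        if tx5_set & tx3_set:
            continue
        ambiguous = len(tx5_set) > 1 or len(tx3_set) > 1
        gap = n - l5 - l3
        for tid5, s5 in hits5:
            for tid3, s3 in hits3:
                calls.append(
                    ChimeraCall(
                        read_id=read.read_id,
                        five_prime=(tid5, s5, s5 + l5),
                        three_prime=(tid3, s3, s3 + l3),
                        l5=l5,
                        l3=l3,
                        gap=gap,
                        ambiguous=ambiguous,
                    )
                )
    return calls


def verify_call(call: ChimeraCall, read: ReadRecord, index: TranscriptIndex) -> bool:
    """Re-check a call by direct string comparison of both segments."""
    t5 = index.by_id[call.five_prime[0]]
    t3 = index.by_id[call.three_prime[0]]
    seg5 = read.seq[: call.l5]
    seg3 = read.seq[len(read) - call.l3 :]
    return (
        t5.seq[call.five_prime[1] : call.five_prime[2]] == seg5
        and t3.seq[call.three_prime[1] : call.three_prime[2]] == seg3
    )
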