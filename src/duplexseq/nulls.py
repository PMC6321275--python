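"""Shuffled-sequence null models and the interaction z-score.

The significance of a read's predicted complementarity to a target is
assessed against composition-preserving shuffles of the read: the native
interaction score is compared to the scores of n shuffled versions, and
z = (native - mean(shuffled)) / sd(shuffled) with the sample (n-1) standard
deviation.  Negative z means the native sequence is more complementary to
the target than its shuffles, i.e. over-represented complementarity.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .energy import DEFAULT_MODEL, EnergyModel
from .duplex import interaction_score


@dataclass(frozen=True)
class ZScoreResult:
    """Native interaction score vs n shuffled scores and the resulting z.

    ``z`` is NaN with ``degenerate=True`` when the shuffled scores have
    zero spread (e.g. a homopolymer read that shuffling cannot alter).
    """

    native_score: float
    shuffled_scores: tuple[float, ...]
    z: float
    degenerate: bool = False

    @property
    def n(self) -> int:
        return len(self.shuffled_scores)


def child_seeds(seed: int, n: int) -> list[int]:
    """Fan a master seed out to n independent child seeds (< 2**31).

    Children are indexed, so requesting more later leaves earlier ones
    unchanged.
    """
    return [
        int(ss.generate_state(1)[0] % 2**31)
        for ss in np.random.SeedSequence(seed).spawn(n)
    ]


def shuffle_sequence(seq: str, mode: str = "mono", seed: int = 0) -> str:
    """Composition-preserving shuffle of an RNA sequence.

    mode="mono": uniform random permutation of the letters (mononucleotide
    composition preserved).  mode="di": Euler-path dinucleotide shuffle
    (Altschul-Erikson), preserving the full dinucleotide count table.
    Deterministic given (seq, mode, seed).  Sequences too short to shuffle
    in di mode (<3 nt) are returned unchanged with a warning.
    """
    if len(seq) < 2:
        raise ValueError("sequence must have length >= 2")
    rng = np.random.default_rng(seed)
    if mode == "mono":
        letters = np.array(list(seq))
        rng.shuffle(letters)
        return "".join(letters)
    if mode != "di":
        raise ValueError(f"unknown shuffle mode {mode!r}")
    if len(seq) < 3:
        warnings.warn("sequence too short for a dinucleotide shuffle; returned as is")
        return seq
    return _dinucleotide_shuffle(seq, rng)


def _dinucleotide_shuffle(seq: str, rng: np.random.Generator) -> str:
    """Altschul-Erikson shuffle: sample a random Eulerian path through the
    dinucleotide multigraph with the original start and end vertices."""
    nodes = sorted(set(seq))
    edges = {c: [] for c in nodes}
    for a, b in zip(seq, seq[1:]):
        edges[a].append(b)
    last = seq[-1]
    while True:
        # pick a random last out-edge for every non-terminal node; the
        # chosen edges must form a tree pointing toward the terminal node
        last_edge = {}
        for c in nodes:
            if c != last and edges[c]:
                last_edge[c] = edges[c][int(rng.integers(len(edges[c])))]
        ok = True
        for c in last_edge:
            seen, cur = {c}, c
            while cur != last:
                if cur not in last_edge:
                    ok = False
                    break
                cur = last_edge[cur]
                if cur in seen:
                    ok = False
                    break
                seen.add(cur)
            if not ok:
                break
        if ok:
            break
    shuffled_edges = {}
    for c in nodes:
        rest = list(edges[c])
        if c in last_edge:
            rest.remove(last_edge[c])
        perm = list(rng.permutation(len(rest)))
        rest = [rest[p] for p in perm]
        if c in last_edge:
            rest.append(last_edge[c])
        shuffled_edges[c] = rest
    # walk the Eulerian path
    out = [seq[0]]
    counters = {c: 0 for c in nodes}
    cur = seq[0]
    for _ in range(len(seq) - 1):
        nxt = shuffled_edges[cur][counters[cur]]
        counters[cur] += 1
        out.append(nxt)
        cur = nxt
    return "".join(out)


def compute_z(native: float, shuffled: Sequence[float]) -> tuple[float, bool]:
    """(z, degenerate): z = (native - mean) / sd with the sample sd.

    Degenerate (z = NaN) when the shuffled scores have zero spread.
    """
    arr = np.asarray(shuffled, dtype=float)
    if arr.size < 2:
        raise ValueError("need at least 2 shuffled scores")
    sd = float(arr.std(ddof=1))
    if sd == 0.0:
        return math.nan, True
    return float((native - arr.mean()) / sd), False


def zscore_interaction(
    read_seq: str,
    target_seq: str,
    model: EnergyModel = DEFAULT_MODEL,
    n: int = 20,
    mode: str = "mono",
    seed: int = 0,
    window_kcal: float = 2.0,
) -> ZScoreResult:
    """z-score of the native read/target interaction score vs n shuffles.

    The read is shuffled; the target stays fixed.  Child seeds derive from
    ``seed`` via a splittable scheme, so changing n does not perturb
    earlier shuffles.
    """
    if n < 2:
        raise ValueError("need at least 2 shuffles")
    native = interaction_score(read_seq, target_seq, model, window_kcal)
    shuffled = []
    for child in child_seeds(seed, n):
        s = shuffle_sequence(read_seq, mode, child)
        shuffled.append(interaction_score(s, target_seq, model, window_kcal))
    z, degenerate = compute_z(native, shuffled)
    return ZScoreResult(native, tuple(shuffled), z, degenerate)


def select_overrepresented(
    results: dict[str, ZScoreResult], cutoff: float = -3.0
) -> list[str]:
    """Transcripts whose z lies strictly below the cutoff.

    Degenerate (NaN-flagged) z-scores are never selected.  Order follows
    the input mapping.
    """
    return [
        tid
        for tid, res in results.items()
        if not res.degenerate and res.z < cutoff
    ]
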