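"""Independent brute-force oracles used to validate the duplex engine.

These deliberately avoid the production dynamic programs: duplex
structures are enumerated as explicit monotone chains of admissible pairs,
and string statistics use the textbook quadratic algorithms.
"""

from __future__ import annotations

from duplexseq.energy import EnergyModel, can_pair

_COMP = {"A": "U", "U": "A", "G": "C", "C": "G"}


def revcomp(seq: str) -> str:
    return "".join(_COMP[c] for c in reversed(seq))


def longest_common_substring(a: str, b: str) -> int:
    """Plain quadratic scan over all start pairs."""
    best = 0
    for i in range(len(a)):
        for j in range(len(b)):
            length = 0
            while i + length < len(a) and j + length < len(b) and a[i + length] == b[j + length]:
                length += 1
            best = max(best, length)
    return best


def chain_energy(
    seq_a: str, rev_b: str, chain: list[tuple[int, int]], model: EnergyModel
) -> float:
    """Energy of an explicit pair chain: initiation plus per-step terms."""
    total = model.helix_init
    for (i1, k1), (i2, k2) in zip(chain, chain[1:]):
        gap_a, gap_b = i2 - i1 - 1, k2 - k1 - 1
        if gap_a == 0 and gap_b == 0:
            total += model.stack((seq_a[i1], rev_b[k1]), (seq_a[i2], rev_b[k2]))
        else:
            total += model.loop_penalty(gap_a, gap_b)
    return total


def enumerate_duplexes(
    seq_a: str, seq_b: str, model: EnergyModel
) -> list[tuple[float, list[tuple[int, int]]]]:
    """Every admissible duplex as (energy, chain) with chain over (i, k),
    k indexing the reversed B strand.  Gaps beyond max_loop terminate a
    structure, matching the model's admissibility."""
    rev_b = seq_b[::-1]
    admissible = [
        (i, k)
        for i in range(len(seq_a))
        for k in range(len(rev_b))
        if can_pair(seq_a[i], rev_b[k], model.allow_gu)
    ]
    out: list[tuple[float, list[tuple[int, int]]]] = []

    def rec(chain: list[tuple[int, int]]) -> None:
        out.append((chain_energy(seq_a, rev_b, chain, model), list(chain)))
        i, k = chain[-1]
        for i2, k2 in admissible:
            if i2 <= i or k2 <= k:
                continue
            if i2 - i - 1 > model.max_loop or k2 - k - 1 > model.max_loop:
                continue
            chain.append((i2, k2))
            rec(chain)
            chain.pop()

    for p in admissible:
        rec([p])
    return out


def footprint(chain: list[tuple[int, int]]) -> tuple[int, int, int, int]:
    return (chain[0][0], chain[-1][0], chain[0][1], chain[-1][1])


def oracle_mfe(seq_a: str, seq_b: str, model: EnergyModel) -> float | None:
    structures = enumerate_duplexes(seq_a, seq_b, model)
    if not structures:
        return None
    return min(e for e, _ in structures)


def oracle_suboptimal(
    seq_a: str, seq_b: str, model: EnergyModel, window: float
) -> dict[tuple[int, int, int, int], float]:
    """Best energy per distinct footprint within the window of the MFE."""
    structures = enumerate_duplexes(seq_a, seq_b, model)
    if not structures:
        return {}
    mfe = min(e for e, _ in structures)
    best: dict[tuple[int, int, int, int], float] = {}
    for e, chain in structures:
        fp = footprint(chain)
        if fp not in best or e < best[fp]:
            best[fp] = e
    return {fp: e for fp, e in best.items() if e <= mfe + window + 1e-9}
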