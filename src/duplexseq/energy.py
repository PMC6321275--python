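"""Nearest-neighbor free-energy model for intermolecular RNA duplexes.

The model covers Watson-Crick and (optionally) G.U wobble pairs at 37 C:
per-stack increments from a shipped TSV table, affine penalties for bulges
and internal loops, and a single duplex-initiation term.  There are no
dangling-end, coaxial-stacking or terminal-AU terms; all downstream
statistics in this package depend only on relative energies.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

WC_PAIRS = frozenset({("A", "U"), ("U", "A"), ("C", "G"), ("G", "C")})
GU_PAIRS = frozenset({("G", "U"), ("U", "G")})


def can_pair(a: str, b: str, allow_gu: bool = True) -> bool:
    p = (a, b)
    return p in WC_PAIRS or (allow_gu and p in GU_PAIRS)


def _load_stack_table() -> dict[tuple[str, str], float]:
    """Load the stack TSV and close it under the symmetry XY/ZW == WZ/YX."""
    table: dict[tuple[str, str], float] = {}
    text = resources.files("duplexseq").joinpath("data/stack_dg37.tsv").read_text()
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#") or line.startswith("motif"):
            continue
        motif, value = line.split("\t")
        top, bottom = motif.split("/")
        dg = float(value)
        table[(top, bottom)] = dg
        sym = (bottom[::-1], top[::-1])
        table.setdefault(sym, dg)
    return table


@dataclass(frozen=True)
class EnergyModel:
    """Duplex energetics: stacks, affine loop penalties, initiation.

    bulge(n)    = bulge_a + bulge_b * (n - 1)          for n >= 1 unpaired nt
    internal(s) = internal_a + internal_b * (s - 2)    for total size s >= 2

    ``max_loop`` caps the unpaired run allowed on either strand between two
    consecutive pairs; larger gaps terminate the duplex instead.
    """

    stack_table: dict[tuple[str, str], float] = field(default_factory=_load_stack_table)
    helix_init: float = 4.09
    bulge_a: float = 3.8
    bulge_b: float = 0.4
    internal_a: float = 1.7
    internal_b: float = 0.35
    max_loop: int = 15
    allow_gu: bool = True

    def stack(self, pair5: tuple[str, str], pair3: tuple[str, str]) -> float:
        """Increment for pair5 stacked 5' of pair3 (both as (top, bottom))."""
        motif = (pair5[0] + pair3[0], pair5[1] + pair3[1])
        return self.stack_table[motif]

    def bulge(self, n: int) -> float:
        if n < 1:
            raise ValueError("bulge length must be >= 1")
        return self.bulge_a + self.bulge_b * (n - 1)

    def internal(self, n1: int, n2: int) -> float:
        if n1 < 1 or n2 < 1:
            raise ValueError("internal loop needs unpaired bases on both strands")
        return self.internal_a + self.internal_b * (n1 + n2 - 2)

    def loop_penalty(self, gap_a: int, gap_b: int) -> float:
        """Penalty for the unpaired runs between two consecutive pairs."""
        if gap_a == 0 and gap_b == 0:
            return 0.0
        if gap_a > self.max_loop or gap_b > self.max_loop:
            raise ValueError("loop exceeds max_loop")
        if gap_a == 0 or gap_b == 0:
            return self.bulge(max(gap_a, gap_b))
        return self.internal(gap_a, gap_b)

    def step(
        self,
        pair5: tuple[str, str],
        pair3: tuple[str, str],
        gap_a: int,
        gap_b: int,
    ) -> float:
        """Cost of extending a duplex from pair5 to pair3 across given gaps."""
        if gap_a == 0 and gap_b == 0:
            return self.stack(pair5, pair3)
        return self.loop_penalty(gap_a, gap_b)


DEFAULT_MODEL = EnergyModel()
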