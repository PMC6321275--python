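"""Intermolecular RNA-RNA duplex prediction.

Three prediction modes over a pair of RNA strands, all restricted to
antiparallel, pseudoknot-free, purely intermolecular pairing (pair indices
strictly increase along strand A and strictly decrease along strand B):

* :func:`longest_complementary_run` - the longest contiguous block of
  perfect (Watson-Crick by default) complementarity; a pure string statistic.
* :func:`max_pairing_duplex` - gap-tolerant alignment maximizing the number
  of base pairs, ties broken toward fewer loops; no energetics.
* :func:`hybrid_mfe` / :func:`suboptimal_duplexes` - minimum-free-energy
  duplex and all structurally distinct duplexes within an energy window
  under the nearest-neighbor :class:`~duplexseq.energy.EnergyModel`.

:func:`interaction_score` sums the MFE and suboptimal energies within the
window (2 kcal/mol by default) into a single complementarity score; more
negative means stronger predicted interaction.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass
from functools import cached_property

import numpy as np

from .energy import DEFAULT_MODEL, EnergyModel, can_pair

_EPS = 1e-9

_BASE_CODE = {"A": 0, "C": 1, "G": 2, "U": 3}
# pair type ids over (top, bottom) letters; -1 = not pairable
_PAIR_LETTERS = [("A", "U"), ("U", "A"), ("C", "G"), ("G", "C"), ("G", "U"), ("U", "G")]
_PAIR_ID = {p: t for t, p in enumerate(_PAIR_LETTERS)}


@dataclass(frozen=True)
class Loop:
    """Unpaired run(s) between two helices: a bulge when one side is empty."""

    len_a: int
    len_b: int

    @property
    def kind(self) -> str:
        return "internal" if self.len_a > 0 and self.len_b > 0 else "bulge"

    @property
    def bulge_strand(self) -> str | None:
        if self.kind != "bulge":
            return None
        return "A" if self.len_a > 0 else "B"


@dataclass(frozen=True)
class DuplexStructure:
    """A predicted intermolecular duplex between strands A and B.

    ``pairs`` lists (i, j): i indexes strand A 5'->3', j indexes strand B
    5'->3'; i strictly increases and j strictly decreases (antiparallel).
    ``energy`` is in kcal/mol and None for pure maximal-pairing mode.
    """

    pairs: tuple[tuple[int, int], ...]
    len_a: int
    len_b: int
    energy: float | None = None

    def __post_init__(self):
        for (i1, j1), (i2, j2) in zip(self.pairs, self.pairs[1:]):
            if not (i2 > i1 and j2 < j1):
                raise ValueError("pairs must increase in i and decrease in j")

    @cached_property
    def helices(self) -> tuple[tuple[int, int, int], ...]:
        """Maximal stacked runs as (startA, startB, length) tuples."""
        if not self.pairs:
            return ()
        out = []
        run_start = 0
        for idx in range(1, len(self.pairs) + 1):
            contiguous = (
                idx < len(self.pairs)
                and self.pairs[idx][0] == self.pairs[idx - 1][0] + 1
                and self.pairs[idx][1] == self.pairs[idx - 1][1] - 1
            )
            if not contiguous:
                i0, j0 = self.pairs[run_start]
                out.append((i0, j0, idx - run_start))
                run_start = idx
        return tuple(out)

    @cached_property
    def loops(self) -> tuple[Loop, ...]:
        out = []
        for (i1, j1), (i2, j2) in zip(self.pairs, self.pairs[1:]):
            gap_a, gap_b = i2 - i1 - 1, j1 - j2 - 1
            if gap_a or gap_b:
                out.append(Loop(gap_a, gap_b))
        return tuple(out)

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    @property
    def longest_helix(self) -> int:
        return max((h[2] for h in self.helices), default=0)

    @property
    def overhang3_a(self) -> int:
        """Unpaired nucleotides 3' of the last pair on strand A."""
        if not self.pairs:
            return self.len_a
        return self.len_a - 1 - self.pairs[-1][0]

    @property
    def overhang3_b(self) -> int:
        """Unpaired nucleotides 3' of the first pair on strand B."""
        if not self.pairs:
            return self.len_b
        return self.len_b - 1 - self.pairs[0][1]

    @property
    def footprint(self) -> tuple[int, int, int, int] | None:
        """(firstA, lastA, firstB_low, firstB_high) paired-interval bounds."""
        if not self.pairs:
            return None
        return (
            self.pairs[0][0],
            self.pairs[-1][0],
            self.pairs[-1][1],
            self.pairs[0][1],
        )

    def swapped(self) -> "DuplexStructure":
        """The same duplex with strand roles exchanged."""
        pairs = tuple(sorted((j, i) for i, j in self.pairs))
        return DuplexStructure(pairs, self.len_b, self.len_a, self.energy)

    def to_lines(self, seq_a: str, seq_b: str) -> str:
        """Two-line inspection rendering: paired bases uppercase, rest lower."""
        a = [c.lower() for c in seq_a]
        b = [c.lower() for c in seq_b]
        for i, j in self.pairs:
            a[i] = seq_a[i].upper()
            b[j] = seq_b[j].upper()
        return "5'-%s-3'\n3'-%s-5'" % ("".join(a), "".join(b)[::-1])


def longest_complementary_run(
    seq_a: str, seq_b: str, allow_gu: bool = False
) -> tuple[int, int, int]:
    """Longest contiguous antiparallel perfectly paired block.

    Returns (length, startA, startB) with 0-based starts of the block on
    each strand (5'->3'); ties resolved toward the smallest startA, then
    smallest startB.  (0, -1, -1) when no pair is possible.  With
    ``allow_gu=False`` this equals the longest common substring of seq_a
    and the reverse complement of seq_b.
    """
    if not seq_a or not seq_b:
        raise ValueError("sequences must be non-empty")
    n, m = len(seq_a), len(seq_b)
    rev_b = seq_b[::-1]
    match = np.zeros((n, m), dtype=bool)
    for (x, y), t in _PAIR_ID.items():
        if not allow_gu and t >= 4:
            continue
        match |= np.outer(
            np.frombuffer(seq_a.encode(), np.uint8) == ord(x),
            np.frombuffer(rev_b.encode(), np.uint8) == ord(y),
        )
    best = (0, -1, -1)
    for d in range(-(m - 1), n):
        diag = np.diagonal(match, offset=-d)
        if not diag.any():
            continue
        # run-length encode the boolean diagonal
        edges = np.flatnonzero(np.diff(np.concatenate(([0], diag.view(np.int8), [0]))))
        starts, ends = edges[::2], edges[1::2]
        for s, e in zip(starts, ends):
            length = int(e - s)
            i0 = (d + s) if d >= 0 else s
            k0 = s if d >= 0 else (-d + s)
            start_a = int(i0)
            start_b = int(m - 1 - (k0 + length - 1))
            cand = (length, start_a, start_b)
            if length > best[0] or (
                length == best[0] and (start_a, start_b) < (best[1], best[2])
            ):
                best = cand
    return best


def _pair_type_matrix(seq_a: str, rev_b: str, allow_gu: bool) -> np.ndarray:
    n, m = len(seq_a), len(rev_b)
    ptype = np.full((n, m), -1, dtype=np.int8)
    limit = 6 if allow_gu else 4
    for (x, y), t in list(_PAIR_ID.items())[:]:
        if t >= limit:
            continue
        ptype[np.ix_(
            np.frombuffer(seq_a.encode(), np.uint8) == ord(x),
            np.frombuffer(rev_b.encode(), np.uint8) == ord(y),
        )] = t
    return ptype


def max_pairing_duplex(seq_a: str, seq_b: str, allow_gu: bool = True) -> DuplexStructure:
    """Gap-tolerant duplex alignment maximizing base pairs, then fewest loops.

    Dynamic program over 'last pair' cells with a running prefix maximum;
    the objective is the lexicographic tuple (pairs, -loops).  Terminal
    unpaired regions (overhangs) are free and are not loops.
    """
    if not seq_a or not seq_b:
        raise ValueError("sequences must be non-empty")
    n, m = len(seq_a), len(seq_b)
    rev_b = seq_b[::-1]
    ptype = _pair_type_matrix(seq_a, rev_b, allow_gu)

    NEG = (-1, 0)
    # M[i][k]: best (pairs, -loops) of a duplex whose last pair is (i, k)
    M = [[NEG] * m for _ in range(n)]
    # P[i][k]: max of M over the rectangle [0..i] x [0..k], with argmax
    P = [[(NEG, (-1, -1))] * m for _ in range(n)]
    back: dict[tuple[int, int], tuple[int, int] | None] = {}

    for i in range(n):
        for k in range(m):
            if ptype[i, k] >= 0:
                best_val, best_from = (1, 0), None
                if i and k:
                    stack_pred = M[i - 1][k - 1]
                    if stack_pred != NEG:
                        cand = (stack_pred[0] + 1, stack_pred[1])
                        if cand > best_val:
                            best_val, best_from = cand, (i - 1, k - 1)
                    rect, arg = P[i - 1][k - 1]
                    if rect != NEG:
                        cand = (rect[0] + 1, rect[1] - 1)
                        if cand > best_val:
                            best_val, best_from = cand, arg
                M[i][k] = best_val
                back[(i, k)] = best_from
            # prefix max (ties keep the earlier, lexicographically smaller cell)
            entries = [(M[i][k], (i, k))]
            if i:
                entries.append(P[i - 1][k])
            if k:
                entries.append(P[i][k - 1])
            P[i][k] = max(entries, key=lambda e: (e[0], (-e[1][0], -e[1][1])))

    best_cell, best_val = None, NEG
    for i in range(n):
        for k in range(m):
            if M[i][k] > best_val:
                best_val, best_cell = M[i][k], (i, k)
    if best_cell is None:
        return DuplexStructure((), n, m, None)
    chain = []
    cell = best_cell
    while cell is not None:
        chain.append(cell)
        cell = back[cell]
    pairs = tuple((i, m - 1 - k) for i, k in reversed(chain))
    return DuplexStructure(pairs, n, m, None)


def _forward_dp(
    seq_a: str, rev_b: str, model: EnergyModel
) -> tuple[np.ndarray, np.ndarray]:
    """E[i,k] = best energy (incl. initiation) of a duplex ending at pair (i,k)."""
    n, m = len(seq_a), len(rev_b)
    ptype = _pair_type_matrix(seq_a, rev_b, model.allow_gu)
    adm = ptype >= 0
    S6 = np.array(
        [
            [model.stack(p5, p3) for p3 in _PAIR_LETTERS]
            for p5 in _PAIR_LETTERS
        ]
    )
    INF = np.inf
    E = np.full((n, m), INF)
    c = model.max_loop
    for i in range(n):
        if not adm[i].any():
            continue
        row = np.full(m, INF)
        if i >= 1:
            # stacking step (di=1, dk=1)
            prev_t = ptype[i - 1, :-1]
            cur_t = ptype[i, 1:]
            ok = (prev_t >= 0) & (cur_t >= 0)
            stack_cost = np.where(
                ok, S6[np.clip(prev_t, 0, 5), np.clip(cur_t, 0, 5)], INF
            )
            row[1:] = np.minimum(row[1:], E[i - 1, :-1] + stack_cost)
            # loop steps
            for di in range(1, min(i, c + 1) + 1):
                for dk in range(1, c + 2):
                    if di == 1 and dk == 1:
                        continue
                    if dk > m:
                        break
                    pen = model.loop_penalty(di - 1, dk - 1)
                    row[dk:] = np.minimum(row[dk:], E[i - di, :-dk] + pen)
        row = np.minimum(row, model.helix_init)
        E[i] = np.where(adm[i], row, INF)
    return E, ptype


def _step_cost(
    model: EnergyModel,
    seq_a: str,
    rev_b: str,
    prev: tuple[int, int],
    cur: tuple[int, int],
) -> float:
    (i1, k1), (i2, k2) = prev, cur
    gap_a, gap_b = i2 - i1 - 1, k2 - k1 - 1
    if gap_a > model.max_loop or gap_b > model.max_loop:
        return np.inf
    pair5 = (seq_a[i1], rev_b[k1])
    pair3 = (seq_a[i2], rev_b[k2])
    if gap_a == 0 and gap_b == 0:
        return model.stack(pair5, pair3)
    return model.loop_penalty(gap_a, gap_b)


def hybrid_mfe(
    seq_a: str, seq_b: str, model: EnergyModel = DEFAULT_MODEL
) -> DuplexStructure:
    """Minimum-free-energy intermolecular duplex under the model.

    Intramolecular pairs are forbidden.  When no admissible pair exists the
    empty structure with energy 0 is returned.  Ties are broken toward the
    lexicographically smallest coordinates.
    """
    if not seq_a or not seq_b:
        raise ValueError("sequences must be non-empty")
    n, m = len(seq_a), len(seq_b)
    rev_b = seq_b[::-1]
    E, ptype = _forward_dp(seq_a, rev_b, model)
    if not np.isfinite(E).any():
        return DuplexStructure((), n, m, 0.0)
    mfe = float(E.min())
    ends = np.argwhere(np.abs(E - mfe) < _EPS)
    i, k = map(int, min(map(tuple, ends)))
    # greedy traceback: re-derive the predecessor achieving each cell value
    chain = [(i, k)]
    value = E[i, k]
    while abs(value - model.helix_init) > _EPS:
        found = False
        for di in range(1, min(i, model.max_loop + 1) + 1):
            for dk in range(1, min(k, model.max_loop + 1) + 1):
                pi, pk = i - di, k - dk
                if ptype[pi, pk] < 0:
                    continue
                cost = _step_cost(model, seq_a, rev_b, (pi, pk), (i, k))
                if abs(E[pi, pk] + cost - value) < 1e-6:
                    chain.append((pi, pk))
                    i, k, value = pi, pk, E[pi, pk]
                    found = True
                    break
            if found:
                break
        if not found:  # numerically at initiation
            break
    pairs = tuple((ii, m - 1 - kk) for ii, kk in reversed(chain))
    return DuplexStructure(pairs, n, m, round(mfe, 10))


def suboptimal_duplexes(
    seq_a: str,
    seq_b: str,
    model: EnergyModel = DEFAULT_MODEL,
    window_kcal: float = 2.0,
) -> list[DuplexStructure]:
    """All structurally distinct duplexes within ``window_kcal`` of the MFE.

    Distinctness is at the level of the paired-interval footprint: one
    representative (the best-energy structure, smallest coordinates on
    ties) per distinct pair of A-interval and B-interval.  Sorted by energy
    ascending, so an MFE structure is element 0.  Empty list when no pair
    is admissible.
    """
    if window_kcal < 0:
        raise ValueError("window_kcal must be >= 0")
    if not seq_a or not seq_b:
        raise ValueError("sequences must be non-empty")
    n, m = len(seq_a), len(seq_b)
    rev_b = seq_b[::-1]
    E, ptype = _forward_dp(seq_a, rev_b, model)
    if not np.isfinite(E).any():
        return []
    mfe = float(E.min())
    bound = mfe + window_kcal + _EPS

    # depth-first enumeration from every admissible last pair, extending
    # toward the 5' end; E[][] gives an exact completion bound for pruning.
    best: dict[tuple, tuple[float, tuple]] = {}
    cand_ends = np.argwhere(E <= bound)
    stack = [((int(i), int(k)), 0.0, ((int(i), int(k)),)) for i, k in cand_ends]
    while stack:
        (i, k), suffix, pairs = stack.pop()
        total = model.helix_init + suffix
        if total <= bound:
            fp = (pairs[-1][0], pairs[0][0], pairs[-1][1], pairs[0][1])
            prev = best.get(fp)
            key = (round(total, 9), pairs[::-1])
            if prev is None or key < prev:
                best[fp] = key
        for di in range(1, min(i, model.max_loop + 1) + 1):
            for dk in range(1, min(k, model.max_loop + 1) + 1):
                pi, pk = i - di, k - dk
                if ptype[pi, pk] < 0:
                    continue
                cost = _step_cost(model, seq_a, rev_b, (pi, pk), (i, k))
                new_suffix = suffix + cost
                if E[pi, pk] + new_suffix > bound:
                    continue
                stack.append(((pi, pk), new_suffix, pairs + ((pi, pk),)))

    out = []
    for fp, (energy, pairs) in best.items():
        struct_pairs = tuple((ii, m - 1 - kk) for ii, kk in pairs)
        out.append(DuplexStructure(struct_pairs, n, m, energy))
    out.sort(key=lambda s: (s.energy, s.footprint))
    return out


def nonoverlapping_sites(structures: list[DuplexStructure]) -> list[DuplexStructure]:
    """Greedy best-energy selection of mutually non-overlapping duplex sites.

    Structures are taken in ascending energy order; one is kept only if its
    paired interval on each strand is disjoint from every already-kept
    structure's interval on that strand.  This collapses the cloud of
    within-window variants of one binding site to its best representative,
    so that a sum over sites counts each site once.
    """
    kept: list[DuplexStructure] = []
    for s in structures:
        i0, i1, j0, j1 = s.footprint
        clash = any(
            i0 <= k.footprint[1] and k.footprint[0] <= i1
            or j0 <= k.footprint[3] and k.footprint[2] <= j1
            for k in kept
        )
        if not clash:
            kept.append(s)
    return kept


def interaction_score(
    seq_a: str,
    seq_b: str,
    model: EnergyModel = DEFAULT_MODEL,
    window_kcal: float = 2.0,
) -> float:
    """Summed energies of the MFE and suboptimal duplex sites in the window.

    The within-window structures are first reduced to non-overlapping site
    representatives (best energy per site), then summed, so each binding
    site - the MFE site included - is counted exactly once.  Without this
    reduction a weak site contributes a combinatorial cloud of
    within-window variants and shallow interactions would outscore a
    single deep site.  0.0 when no duplex is admissible; more negative
    means stronger predicted complementarity.
    """
    subs = suboptimal_duplexes(seq_a, seq_b, model, window_kcal)
    return float(sum(s.energy for s in nonoverlapping_sites(subs)))
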