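"""Synthetic transcriptomes, planted duplexes and nuclease-digested libraries.

The generator emulates the dsRNA-enrichment protocol end to end so every
pipeline stage can be exercised with known ground truth:

* a multi-class transcript pool (high-GC rRNA-like, mRNA, tRNA, lincRNA,
  pseudogene, plus antisense partners that overlap mRNA genes on the
  opposite genomic strand and embed a reverse-complement window);
* planted intermolecular duplexes, 18-40 bp, perfect or carrying a single
  bulge or a single 1x1 mismatch;
* three treatments: ``native`` (protein occlusion masks block duplex
  formation but shield the occluded region from digestion, and digestion
  is less efficient), ``protein_removed`` (heat/formamide reannealing
  pairs every planted region, full nuclease efficiency) and
  ``ribo_removed`` (as protein_removed after discarding rRNA molecules);
* single-strand-specific cleavage 3' of C and U (RNase A-like) and G
  (RNase T1-like), modeled as excision of the cut base; a cleaved defect
  junction severs the complex into its flanking sub-duplexes (strand
  breathing at the defect exposes both backbones);
* 18-50 nt size selection on the digested complexes, with both strands of
  a surviving duplex emitted as independent reads.

Every emitted fragment carries a TruthRecord-style provenance row.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from . import controls
from .seqio import ReadRecord, Transcript, reverse_complement

DEFAULT_CLASSES = ("rRNA", "mRNA", "tRNA", "lincRNA", "pseudogene", "other")

_WOBBLE = {"G": "U", "U": "G"}


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the simulator.

    Defaults model a small but class-complete transcriptome digested under
    the protocol's conditions; probabilities are per molecule (occlusion)
    or per exposed cut base (cleavage).
    """

    n_genes: dict[str, int] = field(
        default_factory=lambda: {
            "rRNA": 2,
            "mRNA": 14,
            "tRNA": 6,
            "lincRNA": 6,
            "pseudogene": 4,
            "other": 2,
        }
    )
    length_ranges: dict[str, tuple[int, int]] = field(
        default_factory=lambda: {
            "rRNA": (1200, 1800),
            "mRNA": (300, 700),
            "tRNA": (70, 90),
            "lincRNA": (250, 600),
            "pseudogene": (200, 500),
            "other": (150, 400),
            "antisense": (200, 450),
        }
    )
    gc_content: dict[str, float] = field(
        default_factory=lambda: {
            "rRNA": 0.80,
            "mRNA": 0.48,
            "tRNA": 0.55,
            "lincRNA": 0.45,
            "pseudogene": 0.45,
            "other": 0.45,
            "antisense": 0.48,
        }
    )
    antisense_pair_fraction: float = 0.5
    n_planted_duplexes: int = 20
    duplex_length_range: tuple[int, int] = (18, 40)
    defect_probs: dict[str, float] = field(
        default_factory=lambda: {"perfect": 0.7, "bulge1": 0.15, "mismatch1": 0.15}
    )
    plant_classes: tuple[str, ...] = ("mRNA", "tRNA", "lincRNA", "pseudogene", "other")
    protein_occlusion: dict[str, float] = field(
        default_factory=lambda: {
            "rRNA": 0.9,
            "mRNA": 0.2,
            "tRNA": 0.2,
            "lincRNA": 0.2,
            "pseudogene": 0.2,
            "other": 0.2,
            "antisense": 0.2,
        }
    )
    native_pairing_block: float = 0.85
    occlusion_window: tuple[int, int] = (25, 45)
    treatment: str = "protein_removed"
    cleavage_prob: float = 1.0
    native_cleavage_prob: float = 0.85
    cut_bases: str = "CUG"
    trim_duplex_flanks: bool = True
    size_window: tuple[int, int] = (18, 50)
    copies_per_transcript: int = 3
    include_spike_ins: bool = False
    spike_copies: int = 1
    master_seed: int = 0

    def __post_init__(self):
        for p in (
            self.antisense_pair_fraction,
            self.cleavage_prob,
            self.native_cleavage_prob,
            self.native_pairing_block,
            *self.protein_occlusion.values(),
            *self.defect_probs.values(),
        ):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability {p} outside [0, 1]")
        if self.size_window[0] >= self.size_window[1]:
            raise ValueError("size_window min must be < max")
        if self.treatment not in ("native", "protein_removed", "ribo_removed"):
            raise ValueError(f"unknown treatment {self.treatment!r}")


@dataclass(frozen=True)
class PlantedWindow:
    """A complementary window embedded between two transcripts.

    (a_start, a_end) on transcript/molecule A; (b_start, b_end) on B; the
    defect lists hold unpaired positions (molecule coordinates) created by
    a bulge (one strand) or mismatch (both strands).
    """

    tx_a: str
    a_start: int
    a_end: int
    tx_b: str
    b_start: int
    b_end: int
    defect: str = "perfect"
    a_defect: tuple[int, ...] = ()
    b_defect: tuple[int, ...] = ()

    def pair_list(self) -> list[tuple[int, int]]:
        """Explicit base pairs: A ascending, B descending, defects skipped."""
        a_positions = [
            i for i in range(self.a_start, self.a_end) if i not in self.a_defect
        ]
        b_positions = [
            j for j in range(self.b_start, self.b_end) if j not in self.b_defect
        ]
        assert len(a_positions) == len(b_positions)
        return list(zip(a_positions, reversed(b_positions)))


@dataclass
class Transcriptome:
    transcripts: list[Transcript]
    windows: list[PlantedWindow]

    def by_id(self) -> dict[str, Transcript]:
        return {t.transcript_id: t for t in self.transcripts}


@dataclass(frozen=True)
class Molecule:
    """One physical RNA copy entering the digestion."""

    molecule_id: str
    transcript_id: str | None
    gene_class: str
    seq: str

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class PlantedDuplex:
    """A planted duplex between two concrete molecules."""

    duplex_id: str
    mol_a: str
    mol_b: str
    window: PlantedWindow


@dataclass
class Fragment:
    """One digestion product piece with its provenance (the truth record)."""

    fragment_id: str
    molecule_id: str
    transcript_id: str | None
    gene_class: str
    start: int
    end: int
    seq: str
    duplex_id: str | None
    defect: str | None
    protected: bool
    complex_size: int
    survived: bool
    three_prime_phosphate: bool

    def __len__(self) -> int:
        return self.end - self.start


def _random_seq(rng: np.random.Generator, length: int, gc: float) -> str:
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list("ACGU"), size=length, p=probs))


def generate_transcriptome(config: SimConfig, seed: int) -> Transcriptome:
    """Draw a class-structured transcriptome with antisense partner genes.

    Antisense partners are attached to a fraction of mRNA genes: their
    genomic interval overlaps the partner's on the opposite strand, and
    their sequence embeds the reverse complement of a window of the
    partner transcript (recorded as a perfect PlantedWindow).  Spike-in
    oligo strands are appended as 'other'-class transcripts on request.
    Same seed, same output bytes.
    """
    rng = np.random.default_rng(seed)
    transcripts: list[Transcript] = []
    windows: list[PlantedWindow] = []
    cursor = 1000  # genomic placement cursor, arbitrary origin
    mrna_ids: list[str] = []
    for cls in DEFAULT_CLASSES:
        for g in range(config.n_genes.get(cls, 0)):
            lo, hi = config.length_ranges[cls]
            length = int(rng.integers(lo, hi + 1))
            seq = _random_seq(rng, length, config.gc_content[cls])
            tid = f"{cls}_{g}"
            transcripts.append(
                Transcript(
                    transcript_id=tid,
                    gene_id=f"gene_{tid}",
                    gene_class=cls,
                    seq=seq,
                    interval=("chr1", cursor, cursor + length, "+"),
                )
            )
            if cls == "mRNA":
                mrna_ids.append(tid)
            cursor += length + 500

    by_id = {t.transcript_id: t for t in transcripts}
    n_antisense = int(round(config.antisense_pair_fraction * len(mrna_ids)))
    partners = list(mrna_ids[:n_antisense])
    for a_idx, mrna_id in enumerate(partners):
        mrna = by_id[mrna_id]
        lo, hi = config.length_ranges["antisense"]
        length = int(rng.integers(lo, min(hi, len(mrna.seq)) + 1))
        w_lo, w_hi = config.duplex_length_range
        w_len = int(rng.integers(w_lo, min(w_hi, length - 2, len(mrna.seq) - 2) + 1))
        m_start = int(rng.integers(0, len(mrna.seq) - w_len + 1))
        a_start = int(rng.integers(0, length - w_len + 1))
        seq = _random_seq(rng, length, config.gc_content["antisense"])
        window_seq = reverse_complement(mrna.seq[m_start : m_start + w_len])
        seq = seq[:a_start] + window_seq + seq[a_start + w_len :]
        # opposite-strand interval inside the partner gene's span
        chrom, g_start, g_end, _ = mrna.interval
        offset = int(rng.integers(0, max(g_end - g_start - length, 1)))
        iv_start = g_start + offset
        tid = f"antisense_{a_idx}"
        transcripts.append(
            Transcript(
                transcript_id=tid,
                gene_id=f"gene_{tid}",
                gene_class="antisense",
                seq=seq,
                interval=(chrom, iv_start, iv_start + length, "-"),
            )
        )
        windows.append(
            PlantedWindow(
                tx_a=mrna_id,
                a_start=m_start,
                a_end=m_start + w_len,
                tx_b=tid,
                b_start=a_start,
                b_end=a_start + w_len,
            )
        )

    if config.include_spike_ins:
        for name, seq in controls.SPIKE_IN_OLIGOS.items():
            transcripts.append(
                Transcript(
                    transcript_id=f"spike_{name}",
                    gene_id=f"gene_spike_{name}",
                    gene_class="other",
                    seq=seq,
                    interval=("spike", 0, len(seq), "+"),
                )
            )
    return Transcriptome(transcripts, windows)


def plant_duplexes(
    transcriptome: Transcriptome, config: SimConfig, seed: int
) -> tuple[Transcriptome, list[Molecule], list[PlantedDuplex]]:
    """Embed additional planted duplexes and instantiate molecules.

    Antisense windows from the generator are kept as planted duplexes.
    ``n_planted_duplexes`` extra windows are drawn between random
    transcript pairs of the plant classes (region collisions re-drawn with
    bounded retries), with defects sampled from ``defect_probs``; the
    reverse-complement window is spliced into the B-side transcript so
    that digested reads still map exactly.  Every transcript is then
    instantiated ``copies_per_transcript`` times, and each window yields
    one duplex per copy index.  Spike-in pairs A/B (perfect), A/C (bulge),
    A/D (1x1 loop) are registered when the transcriptome carries them.
    """
    rng = np.random.default_rng(seed)
    by_id = dict(transcriptome.by_id())
    windows = list(transcriptome.windows)

    def occupied(tid: str) -> list[tuple[int, int]]:
        spans = []
        for w in windows:
            if w.tx_a == tid:
                spans.append((w.a_start, w.a_end))
            if w.tx_b == tid:
                spans.append((w.b_start, w.b_end))
        return spans

    candidates = [
        t.transcript_id
        for t in transcriptome.transcripts
        if t.gene_class in config.plant_classes and not t.transcript_id.startswith("spike_")
    ]
    defects = list(config.defect_probs)
    defect_p = np.array([config.defect_probs[d] for d in defects])
    defect_p = defect_p / defect_p.sum()
    planted = 0
    attempts = 0
    while planted < config.n_planted_duplexes and attempts < 200 * config.n_planted_duplexes:
        attempts += 1
        tid_a, tid_b = rng.choice(candidates, size=2, replace=False)
        tx_a, tx_b = by_id[tid_a], by_id[tid_b]
        w_lo, w_hi = config.duplex_length_range
        max_len = min(w_hi, len(tx_a.seq) - 2, len(tx_b.seq) - 2)
        if max_len < w_lo:
            continue
        w_len = int(rng.integers(w_lo, max_len + 1))
        a_start = int(rng.integers(0, len(tx_a.seq) - w_len + 1))
        b_start = int(rng.integers(0, len(tx_b.seq) - w_len + 1))
        spans_a = occupied(tid_a)
        spans_b = occupied(tid_b)
        if any(a_start < e and s < a_start + w_len for s, e in spans_a):
            continue
        if any(b_start < e and s < b_start + w_len for s, e in spans_b):
            continue
        window_seq = reverse_complement(tx_a.seq[a_start : a_start + w_len])
        new_b_seq = tx_b.seq[:b_start] + window_seq + tx_b.seq[b_start + w_len :]
        window = PlantedWindow(tid_a, a_start, a_start + w_len, tid_b, b_start, b_start + w_len)
        defect = defects[int(rng.choice(len(defects), p=defect_p))]
        if defect == "bulge1":
            mid_b = (window.b_start + window.b_end) // 2
            extra = "ACGU"[int(rng.integers(4))]
            new_b_seq = new_b_seq[:mid_b] + extra + new_b_seq[mid_b:]
            window = replace(window, b_end=window.b_end + 1, defect="bulge1", b_defect=(mid_b,))
            # the insertion shifts every coordinate downstream of mid_b on
            # this transcript; renumber previously planted windows there
            windows = [_shift_window(w2, tid_b, mid_b) for w2 in windows]
        elif defect == "mismatch1":
            mid_b = (window.b_start + window.b_end) // 2
            offset = mid_b - window.b_start
            a_pos = window.a_end - 1 - offset
            a_base = tx_a.seq[a_pos]
            comp = reverse_complement(a_base)
            banned = {comp, _WOBBLE.get(a_base, "")}
            choicepool = [c for c in "ACGU" if c not in banned]
            sub = choicepool[int(rng.integers(len(choicepool)))]
            new_b_seq = new_b_seq[:mid_b] + sub + new_b_seq[mid_b + 1 :]
            window = replace(window, defect="mismatch1", a_defect=(a_pos,), b_defect=(mid_b,))
        chrom, s, e, strand = tx_b.interval
        by_id[tid_b] = Transcript(
            tx_b.transcript_id,
            tx_b.gene_id,
            tx_b.gene_class,
            new_b_seq,
            (chrom, s, s + len(new_b_seq), strand),
        )
        windows.append(window)
        planted += 1

    new_transcriptome = Transcriptome(
        [by_id[t.transcript_id] for t in transcriptome.transcripts], windows
    )

    molecules: list[Molecule] = []
    duplexes: list[PlantedDuplex] = []
    for t in new_transcriptome.transcripts:
        if t.transcript_id.startswith("spike_"):
            continue
        for c in range(config.copies_per_transcript):
            molecules.append(
                Molecule(f"{t.transcript_id}@{c}", t.transcript_id, t.gene_class, t.seq)
            )
    for w_idx, w in enumerate(windows):
        for c in range(config.copies_per_transcript):
            duplexes.append(
                PlantedDuplex(f"dx{w_idx}@{c}", f"{w.tx_a}@{c}", f"{w.tx_b}@{c}", w)
            )

    if config.include_spike_ins:
        spike_pairs = [("A", "B"), ("A", "C"), ("A", "D")]
        for c in range(config.spike_copies):
            for p_idx, (x, y) in enumerate(spike_pairs):
                mol_x = Molecule(
                    f"spike_{x}/{p_idx}.{c}", f"spike_{x}", "other", controls.SPIKE_IN_OLIGOS[x]
                )
                mol_y = Molecule(
                    f"spike_{y}/{p_idx}.{c}", f"spike_{y}", "other", controls.SPIKE_IN_OLIGOS[y]
                )
                molecules.extend([mol_x, mol_y])
                duplexes.append(
                    PlantedDuplex(
                        f"spike_dx{p_idx}.{c}",
                        mol_x.molecule_id,
                        mol_y.molecule_id,
                        spike_in_window(y),
                    )
                )
    return new_transcriptome, molecules, duplexes


def _shift_window(w: PlantedWindow, tid: str, at: int, by: int = 1) -> PlantedWindow:
    """Renumber a window's coordinates on ``tid`` after an insertion at ``at``."""
    out = w
    if w.tx_a == tid and w.a_start >= at:
        out = replace(
            out,
            a_start=out.a_start + by,
            a_end=out.a_end + by,
            a_defect=tuple(p + by for p in out.a_defect),
        )
    if w.tx_b == tid and w.b_start >= at:
        out = replace(
            out,
            b_start=out.b_start + by,
            b_end=out.b_end + by,
            b_defect=tuple(p + by for p in out.b_defect),
        )
    return out


def spike_in_window(partner: str) -> PlantedWindow:
    """The planted window describing the A/B, A/C or A/D spike-in duplex."""
    if partner == "B":
        return PlantedWindow("spike_A", 0, 30, "spike_B", 0, 30)
    if partner == "C":
        return PlantedWindow(
            "spike_A", 0, 30, "spike_C", 0, 31, defect="bulge1", b_defect=(16,)
        )
    if partner == "D":
        return PlantedWindow(
            "spike_A", 0, 30, "spike_D", 0, 30,
            defect="mismatch1", a_defect=(13,), b_defect=(16,),
        )
    raise ValueError(f"no spike-in duplex with partner {partner!r}")


def simulate_digestion(
    molecules: Sequence[Molecule],
    duplexes: Sequence[PlantedDuplex],
    config: SimConfig,
    seed: int,
) -> list[Fragment]:
    """Digest molecules with single-strand-specific nucleases.

    Returns all resulting pieces as Fragments with ``survived`` marking the
    18-50 size selection.  See the module docstring for the treatment
    semantics.  Deterministic given (inputs, config, seed).
    """
    rng = np.random.default_rng(seed)
    treatment = config.treatment
    mols = {m.molecule_id: m for m in molecules}
    if treatment == "ribo_removed":
        mols = {k: m for k, m in mols.items() if m.gene_class != "rRNA"}
    active_duplexes = [
        d for d in duplexes if d.mol_a in mols and d.mol_b in mols
    ]
    cleave_p = (
        config.native_cleavage_prob if treatment == "native" else config.cleavage_prob
    )

    paired: dict[str, np.ndarray] = {
        k: np.zeros(len(m), dtype=bool) for k, m in mols.items()
    }
    protected: dict[str, np.ndarray] = {
        k: np.zeros(len(m), dtype=bool) for k, m in mols.items()
    }
    # pair partner bookkeeping: molecule position -> (partner mol, partner pos, duplex)
    pair_partner: dict[str, dict[int, tuple[str, int, str]]] = {
        k: {} for k in mols
    }
    formed: list[PlantedDuplex] = []
    occluded_duplex: set[str] = set()

    for d in active_duplexes:
        w = d.window
        if treatment == "native":
            # protein binding blocks pairing; a blocked region may still be
            # shielded from the nuclease by the bound protein
            if rng.random() < config.native_pairing_block:
                occluded_duplex.add(d.duplex_id)
                if rng.random() < config.protein_occlusion.get(
                    mols[d.mol_a].gene_class, 0.0
                ):
                    protected[d.mol_a][w.a_start : w.a_end] = True
                if rng.random() < config.protein_occlusion.get(
                    mols[d.mol_b].gene_class, 0.0
                ):
                    protected[d.mol_b][w.b_start : w.b_end] = True
                continue
        formed.append(d)
        for (ai, bj) in w.pair_list():
            paired[d.mol_a][ai] = True
            paired[d.mol_b][bj] = True
            pair_partner[d.mol_a][ai] = (d.mol_b, bj, d.duplex_id)
            pair_partner[d.mol_b][bj] = (d.mol_a, ai, d.duplex_id)

    if treatment == "native":
        # protein occlusion of molecules outside planted regions: a random
        # window escapes digestion (the main source of native-library reads)
        planted_mols = {d.mol_a for d in active_duplexes} | {
            d.mol_b for d in active_duplexes
        }
        for k, m in mols.items():
            if k in planted_mols:
                continue
            p_occ = config.protein_occlusion.get(m.gene_class, 0.0)
            if rng.random() < p_occ:
                lo, hi = config.occlusion_window
                w_len = min(int(rng.integers(lo, hi + 1)), len(m))
                start = int(rng.integers(0, len(m) - w_len + 1))
                protected[k][start : start + w_len] = True

    # single-strand cleavage: excise exposed cut bases
    removed: dict[str, np.ndarray] = {}
    cut_set = set(config.cut_bases)
    for k, m in mols.items():
        exposed = np.array(
            [
                (c in cut_set) and not paired[k][i] and not protected[k][i]
                for i, c in enumerate(m.seq)
            ]
        )
        draws = rng.random(len(m)) < cleave_p
        removed[k] = exposed & draws

    # defect junctions: cleavage severs both strands at the junction
    severed: dict[str, set[int]] = {k: set() for k in mols}  # cut between pos and pos+1
    for d in formed:
        w = d.window
        if w.defect == "perfect":
            continue
        junction_protected = bool(
            (protected[d.mol_a][w.a_start : w.a_end].any())
            or (protected[d.mol_b][w.b_start : w.b_end].any())
        )
        if junction_protected or rng.random() >= cleave_p:
            continue
        for pos in w.a_defect:
            removed[d.mol_a][pos] = True
        for pos in w.b_defect:
            removed[d.mol_b][pos] = True
        if not w.a_defect:  # bulge on B: sever A's backbone between the helices
            b_def = w.b_defect[0]
            # A positions pairing the bases flanking the bulge
            pairs = w.pair_list()
            left = max(ai for ai, bj in pairs if bj > b_def)
            severed[d.mol_a].add(left)
        if not w.b_defect:
            a_def = w.a_defect[0]
            pairs = w.pair_list()
            left = max(bj for ai, bj in pairs if ai > a_def)
            severed[d.mol_b].add(left)

    # fragment molecules into maximal retained runs
    pieces: dict[str, list[tuple[int, int]]] = {}
    for k, m in mols.items():
        runs = []
        start = None
        for i in range(len(m) + 1):
            gone = i == len(m) or removed[k][i]
            if start is None and not gone:
                start = i
            if start is not None and gone:
                runs.append((start, i))
                start = None
            if start is not None and i < len(m) and i in severed[k]:
                runs.append((start, i + 1))
                start = None
        pieces[k] = runs

    # trim single-stranded tails off duplex-containing pieces: accessible
    # tails carry cut sites and breathe, so complete digestion removes them
    if config.trim_duplex_flanks:
        for k in mols:
            trimmed_runs = []
            for s, e in pieces[k]:
                paired_pos = [i for i in range(s, e) if paired[k][i]]
                if paired_pos:
                    s2, e2 = paired_pos[0], paired_pos[-1] + 1
                    removed[k][s:s2] = True
                    removed[k][e2:e] = True
                    trimmed_runs.append((s2, e2))
                else:
                    trimmed_runs.append((s, e))
            pieces[k] = trimmed_runs

    # group pieces into complexes via surviving base pairs
    piece_id = {}
    for k, runs in pieces.items():
        for idx, (s, e) in enumerate(runs):
            piece_id[(k, idx)] = len(piece_id)
    parent = list(range(len(piece_id)))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(x: int, y: int) -> None:
        parent[find(x)] = find(y)

    def piece_of(k: str, pos: int) -> int | None:
        for idx, (s, e) in enumerate(pieces[k]):
            if s <= pos < e:
                return idx
        return None

    piece_duplex: dict[int, str] = {}
    for k in mols:
        for pos, (pk, ppos, dxid) in pair_partner[k].items():
            if removed[k][pos] or removed[pk][ppos]:
                continue
            pa = piece_of(k, pos)
            pb = piece_of(pk, ppos)
            if pa is None or pb is None:
                continue
            ida, idb = piece_id[(k, pa)], piece_id[(pk, pb)]
            union(ida, idb)
            piece_duplex[ida] = dxid
            piece_duplex[idb] = dxid

    complex_sizes: dict[int, int] = {}
    root_duplex: dict[int, str] = {}
    for pid, dxid in piece_duplex.items():
        root_duplex[find(pid)] = dxid
    for (k, idx), pid in piece_id.items():
        root = find(pid)
        s, e = pieces[k][idx]
        complex_sizes[root] = max(complex_sizes.get(root, 0), e - s)

    duplex_by_id = {d.duplex_id: d for d in duplexes}
    lo, hi = config.size_window
    fragments: list[Fragment] = []
    for (k, idx), pid in sorted(piece_id.items()):
        s, e = pieces[k][idx]
        m = mols[k]
        root = find(pid)
        size = complex_sizes[root]
        dxid = root_duplex.get(root)
        defect = duplex_by_id[dxid].window.defect if dxid else None
        fragments.append(
            Fragment(
                fragment_id=f"{k}:{s}-{e}",
                molecule_id=k,
                transcript_id=m.transcript_id,
                gene_class=m.gene_class,
                start=s,
                end=e,
                seq=m.seq[s:e],
                duplex_id=dxid,
                defect=defect,
                protected=bool(protected[k][s:e].any()),
                complex_size=size,
                survived=lo <= size <= hi,
                three_prime_phosphate=e < len(m),
            )
        )
    return fragments


def emit_library(
    fragments: Sequence[Fragment], config: SimConfig
) -> tuple[list[ReadRecord], pd.DataFrame]:
    """Turn surviving fragments into reads plus a truth table for all pieces.

    One read per surviving fragment strand with uniform Phred-40
    qualities; read IDs equal fragment IDs.  The truth DataFrame covers
    every fragment, survived or not.
    """
    reads = [
        ReadRecord(f.fragment_id, f.seq, (40,) * len(f.seq))
        for f in fragments
        if f.survived
    ]
    truth = pd.DataFrame(
        [
            {
                "fragment_id": f.fragment_id,
                "molecule_id": f.molecule_id,
                "transcript_id": f.transcript_id,
                "gene_class": f.gene_class,
                "start": f.start,
                "end": f.end,
                "length": len(f),
                "duplex_id": f.duplex_id,
                "defect": f.defect,
                "protected": f.protected,
                "complex_size": f.complex_size,
                "survived": f.survived,
                "three_prime_phosphate": f.three_prime_phosphate,
            }
            for f in fragments
        ]
    )
    return reads, truth


def simulate_library(
    config: SimConfig, seed: int | None = None
) -> tuple[Transcriptome, list[ReadRecord], pd.DataFrame]:
    """Convenience end-to-end run: transcriptome -> plants -> digestion -> reads.

    Child seeds for the three stages derive from ``seed`` (defaults to
    ``config.master_seed``) so the stages stay independently reproducible.
    """
    from .nulls import child_seeds

    master = config.master_seed if seed is None else seed
    s_tx, s_plant, s_digest = child_seeds(master, 3)
    transcriptome = generate_transcriptome(config, s_tx)
    transcriptome, molecules, duplexes = plant_duplexes(transcriptome, config, s_plant)
    fragments = simulate_digestion(molecules, duplexes, config, s_digest)
    reads, truth = emit_library(fragments, config)
    return transcriptome, reads, truth


def anti_complementary_codebook(
    n_reads: int = 30,
    length: int = 22,
    max_run: int = 5,
    seed: int = 0,
    gc: float = 0.5,
) -> list[ReadRecord]:
    """Reads designed so that no two share a complementary block > max_run.

    Rejection sampling against the longest perfectly complementary run,
    checked against every accepted read and against the read itself
    (self-complementarity).  Shuffling such a codebook restores chance
    complementarity, so a shuffled-control scan yields longer helices than
    the designed reads.
    """
    from .duplex import longest_complementary_run

    rng = np.random.default_rng(seed)
    reads: list[ReadRecord] = []
    attempts = 0
    while len(reads) < n_reads:
        attempts += 1
        if attempts > 2000 * n_reads:
            raise RuntimeError("codebook design failed; relax max_run or n_reads")
        seq = _random_seq(rng, length, gc)
        if longest_complementary_run(seq, seq)[0] > max_run:
            continue
        if any(
            longest_complementary_run(seq, r.seq)[0] > max_run for r in reads
        ):
            continue
        reads.append(ReadRecord(f"code_{len(reads)}", seq, (40,) * length))
    return reads


def simulate_contingency_datasets(
    n_datasets: int = 13,
    n_genes: int = 2000,
    overlap_fraction: float = 0.25,
    base_match_rate: float = 0.15,
    relative_risk: float = 2.4,
    seed: int = 0,
):
    """Contingency tables with a planted relative risk, for recovery tests.

    Each dataset draws per-gene antisense-overlap flags at
    ``overlap_fraction`` and read-match flags with probability
    ``base_match_rate`` (no overlap) or ``relative_risk`` times that
    (overlap).  Returns a list of ContingencyTable.
    """
    from .antisense import ContingencyTable
    from .nulls import child_seeds

    if base_match_rate * relative_risk > 1.0:
        raise ValueError("overlap match probability exceeds 1")
    tables = []
    for i, s in enumerate(child_seeds(seed, n_datasets)):
        rng = np.random.default_rng(s)
        overlap = rng.random(n_genes) < overlap_fraction
        p = np.where(overlap, base_match_rate * relative_risk, base_match_rate)
        match = rng.random(n_genes) < p
        tables.append(
            ContingencyTable(
                a=int((overlap & match).sum()),
                b=int((overlap & ~match).sum()),
                c=int((~overlap & match).sum()),
                d=int((~overlap & ~match).sum()),
                dataset_label=f"sim_{i}",
            )
        )
    return tables
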