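import numpy as np
import pandas as pd
import pytest

from duplexseq.antisense import annotate_antisense_overlap
from duplexseq.duplex import max_pairing_duplex
from duplexseq.scan import all_vs_all_scan, scan_summary, shuffled_control_scan
from duplexseq.seqio import gc_fraction, length_filter
from duplexseq.simulate import (
    Molecule,
    PlantedDuplex,
    SimConfig,
    anti_complementary_codebook,
    emit_library,
    generate_transcriptome,
    plant_duplexes,
    simulate_digestion,
    simulate_library,
    spike_in_window,
)


def spike_only_config(**kwargs):
    empty = {c: 0 for c in ("rRNA", "mRNA", "tRNA", "lincRNA", "pseudogene", "other")}
    defaults = dict(
        n_genes=empty,
        antisense_pair_fraction=0.0,
        n_planted_duplexes=0,
        include_spike_ins=True,
        cleavage_prob=1.0,
    )
    defaults.update(kwargs)
    return SimConfig(**defaults)


def run_sim(config, seeds=(1, 2, 3)):
    txome = generate_transcriptome(config, seeds[0])
    txome, mols, dups = plant_duplexes(txome, config, seeds[1])
    frags = simulate_digestion(mols, dups, config, seeds[2])
    return txome, mols, dups, frags


class TestGenerateTranscriptome:
    def test_deterministic(self):
        config = SimConfig()
        t1 = generate_transcriptome(config, 5)
        t2 = generate_transcriptome(config, 5)
        assert [x.seq for x in t1.transcripts] == [x.seq for x in t2.transcripts]
        assert t1.windows == t2.windows

    def test_rrna_gc_hits_target(self):
        config = SimConfig(
            n_genes={"rRNA": 1},
            length_ranges={"rRNA": (5000, 5000), "antisense": (200, 400)},
        )
        txome = generate_transcriptome(config, 3)
        rrna = [t for t in txome.transcripts if t.gene_class == "rRNA"][0]
        assert abs(gc_fraction(rrna.seq) - 0.80) < 0.05

    def test_zero_antisense_fraction_no_overlaps(self):
        config = SimConfig(antisense_pair_fraction=0.0)
        txome = generate_transcriptome(config, 4)
        flags = annotate_antisense_overlap(txome.transcripts)
        assert not any(flags.values())

    def test_antisense_partners_overlap_and_complement(self):
        config = SimConfig(antisense_pair_fraction=1.0)
        txome = generate_transcriptome(config, 6)
        flags = annotate_antisense_overlap(txome.transcripts)
        by_id = txome.by_id()
        assert txome.windows
        for w in txome.windows:
            assert flags[by_id[w.tx_a].gene_id] and flags[by_id[w.tx_b].gene_id]
            a_seg = by_id[w.tx_a].seq[w.a_start : w.a_end]
            d = max_pairing_duplex(a_seg, by_id[w.tx_b].seq[w.b_start : w.b_end])
            assert d.n_pairs == len(a_seg)


class TestPlantDuplexes:
    def test_planted_windows_pair_perfectly_or_with_one_defect(self):
        config = SimConfig(n_planted_duplexes=8)
        txome = generate_transcriptome(config, 7)
        txome, mols, dups = plant_duplexes(txome, config, 8)
        by_id = txome.by_id()
        seen_defects = set()
        for w in txome.windows:
            a_seg = by_id[w.tx_a].seq[w.a_start : w.a_end]
            b_seg = by_id[w.tx_b].seq[w.b_start : w.b_end]
            d = max_pairing_duplex(a_seg, b_seg, allow_gu=False)
            seen_defects.add(w.defect)
            if w.defect == "perfect":
                assert d.n_pairs == len(a_seg)
                assert d.loops == ()
            elif w.defect == "bulge1":
                assert d.n_pairs == len(a_seg)
                assert [lp.kind for lp in d.loops] == ["bulge"]
            elif w.defect == "mismatch1":
                assert d.n_pairs == len(a_seg) - 1
                assert [lp.kind for lp in d.loops] == ["internal"]
        assert "perfect" in seen_defects

    def test_one_duplex_per_window_per_copy(self):
        config = SimConfig(n_planted_duplexes=5, copies_per_transcript=2)
        txome = generate_transcriptome(config, 1)
        txome, mols, dups = plant_duplexes(txome, config, 2)
        assert len(dups) == len(txome.windows) * 2

    def test_reads_from_planted_regions_map_back(self):
        # planted windows are spliced into the transcript sequence itself
        config = SimConfig(n_planted_duplexes=6)
        txome = generate_transcriptome(config, 9)
        txome, mols, dups = plant_duplexes(txome, config, 10)
        by_tx = txome.by_id()
        for m in mols:
            assert m.seq == by_tx[m.transcript_id].seq


class TestDigestion:
    def test_perfect_spike_survives_as_trimmed_duplex(self):
        config = spike_only_config(treatment="protein_removed")
        _, mols, dups, frags = run_sim(config)
        ab = [f for f in frags if f.survived and f.molecule_id.startswith(("spike_A/0", "spike_B/0"))]
        assert sorted(len(f) for f in ab) == [30, 30]
        assert all(f.complex_size == 30 for f in ab)

    def test_defective_spikes_yield_nothing_over_18(self):
        config = spike_only_config(treatment="protein_removed")
        _, mols, dups, frags = run_sim(config)
        defect_frags = [f for f in frags if f.defect in ("bulge1", "mismatch1")]
        assert defect_frags  # the pieces exist...
        assert not [f for f in defect_frags if f.survived]  # ...but none pass 18-50

    def test_bulge_splits_sixteen_fourteen(self):
        config = spike_only_config(treatment="protein_removed")
        _, mols, dups, frags = run_sim(config)
        c_pieces = sorted(
            len(f) for f in frags if f.molecule_id.startswith("spike_C")
        )
        assert c_pieces == [14, 16]

    def test_native_occlusion_lets_defect_duplexes_partially_survive(self):
        config = spike_only_config(
            treatment="native",
            spike_copies=60,
            native_cleavage_prob=0.85,
            protein_occlusion={"other": 0.5},
        )
        _, mols, dups, frags = run_sim(config)
        survivors = [
            f for f in frags if f.survived and f.defect in ("bulge1", "mismatch1")
        ]
        assert survivors  # partial survival, unlike full digestion

    def test_pure_ssrna_fully_digested_unless_polya(self):
        mols = [
            Molecule("m1", None, "mRNA", "ACGUGCUAGCUAGGCUAGCAUCGGAUCGAUGCAU"),
            Molecule("m2", None, "mRNA", "A" * 25),
        ]
        config = SimConfig(treatment="protein_removed", cleavage_prob=1.0)
        frags = simulate_digestion(mols, [], config, 5)
        survived = [f for f in frags if f.survived]
        assert [f.molecule_id for f in survived] == ["m2"]

    def test_conservation_every_base_in_exactly_one_piece(self):
        config = SimConfig(master_seed=3)
        txome = generate_transcriptome(config, 3)
        txome, mols, dups = plant_duplexes(txome, config, 4)
        frags = simulate_digestion(mols, dups, config, 5)
        by_mol = {}
        for f in frags:
            by_mol.setdefault(f.molecule_id, []).append((f.start, f.end))
        for mol_id, spans in by_mol.items():
            spans.sort()
            for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
                assert e1 <= s2  # disjoint
        mol_len = {m.molecule_id: len(m) for m in mols}
        for mol_id, spans in by_mol.items():
            assert all(0 <= s < e <= mol_len[mol_id] for s, e in spans)

    def test_ribo_removed_has_no_rrna_fragments(self):
        config = SimConfig(treatment="ribo_removed", master_seed=11)
        _, reads, truth = simulate_library(config)
        assert not (truth.gene_class == "rRNA").any()

    def test_native_fewer_long_duplex_fragments_than_protein_removed(self):
        for seed in (1, 2):
            frames = {}
            for treatment in ("native", "protein_removed"):
                config = SimConfig(treatment=treatment, master_seed=seed)
                _, reads, truth = simulate_library(config)
                frames[treatment] = truth
            def n_duplex(t):
                return int(
                    (t.survived & t.duplex_id.notna() & (t.length >= 18)).sum()
                )
            assert n_duplex(frames["native"]) < n_duplex(frames["protein_removed"])

    def test_no_plants_no_survivors_under_full_cleavage(self):
        config = SimConfig(
            n_planted_duplexes=0,
            antisense_pair_fraction=0.0,
            treatment="protein_removed",
            cleavage_prob=1.0,
            master_seed=2,
        )
        _, reads, truth = simulate_library(config)
        # only stochastic cut-free runs (e.g. poly-A stretches) could survive
        assert len(reads) <= 2


class TestEmitLibrary:
    def test_two_reads_per_surviving_duplex(self):
        config = spike_only_config(treatment="protein_removed", spike_copies=4)
        _, mols, dups, frags = run_sim(config)
        reads, truth = emit_library(frags, config)
        surviving_duplexes = truth[truth.survived].duplex_id.dropna().unique()
        assert len(reads) == 2 * len(surviving_duplexes)

    def test_empty_input_valid_empty_library(self):
        reads, truth = emit_library([], SimConfig())
        assert reads == [] and truth.empty

    def test_byte_determinism(self):
        config = SimConfig(master_seed=8)
        _, r1, t1 = simulate_library(config)
        _, r2, t2 = simulate_library(config)
        assert r1 == r2
        pd.testing.assert_frame_equal(t1, t2)


class TestCodebook:
    def test_no_pair_shares_long_complement(self):
        from duplexseq.duplex import longest_complementary_run

        reads = anti_complementary_codebook(n_reads=12, length=22, max_run=5, seed=4)
        for i in range(len(reads)):
            assert longest_complementary_run(reads[i].seq, reads[i].seq)[0] <= 5
            for j in range(i + 1, len(reads)):
                assert longest_complementary_run(reads[i].seq, reads[j].seq)[0] <= 5

    def test_shuffling_restores_chance_complementarity(self):
        reads = anti_complementary_codebook(n_reads=25, length=22, max_run=5, seed=7)
        plain = scan_summary(all_vs_all_scan(reads, engine="max_pairing"))[0]
        shuffled = scan_summary(
            shuffled_control_scan(reads, engine="max_pairing", seed=7)
        )[0]
        assert plain <= 5
        assert shuffled >= plain


class TestSpikeWindows:
    def test_windows_reproduce_engineered_geometry(self):
        w_ab = spike_in_window("B")
        assert (w_ab.a_end - w_ab.a_start, w_ab.defect) == (30, "perfect")
        assert len(spike_in_window("C").pair_list()) == 30
        assert len(spike_in_window("D").pair_list()) == 29
        with pytest.raises(ValueError):
            spike_in_window("Z")
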