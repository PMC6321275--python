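import numpy as np
import pytest

from duplexseq.controls import SPIKE_IN_A, SPIKE_IN_B, SPIKE_IN_C, SPIKE_IN_D
from duplexseq.duplex import (
    DuplexStructure,
    hybrid_mfe,
    interaction_score,
    longest_complementary_run,
    max_pairing_duplex,
    suboptimal_duplexes,
)
from duplexseq.energy import WC_PAIRS, EnergyModel

import oracles
from conftest import random_rna


def impl_footprints(structures, len_b):
    """Map implementation footprints into the oracle's (i, k) convention."""
    out = {}
    for s in structures:
        i0, i1, j_lo, j_hi = s.footprint
        out[(i0, i1, len_b - 1 - j_hi, len_b - 1 - j_lo)] = s.energy
    return out


class TestEnergyModel:
    def test_wc_stacks_negative_and_symmetric(self, model):
        for p in WC_PAIRS:
            for q in WC_PAIRS:
                dg = model.stack(p, q)
                assert dg < 0
                # physical symmetry: reading the duplex from the other strand
                assert model.stack((q[1], q[0]), (p[1], p[0])) == dg

    def test_loop_penalties_nonneg_nondecreasing(self, model):
        bulges = [model.bulge(n) for n in range(1, 8)]
        assert all(b >= 0 for b in bulges)
        assert bulges == sorted(bulges)
        internals = [model.internal(1, n) for n in range(1, 8)]
        assert internals == sorted(internals)
        assert model.loop_penalty(0, 0) == 0.0


class TestOligoWorkedExamples:
    """Structural classification of the three spike-in constructs."""

    def test_a_b_perfect_30bp_with_5nt_overhangs(self):
        d = max_pairing_duplex(SPIKE_IN_A, SPIKE_IN_B)
        assert d.n_pairs == 30
        assert d.loops == ()
        assert d.longest_helix == 30
        assert d.overhang3_a == 5 and d.overhang3_b == 5

    def test_a_c_single_bulge(self):
        d = max_pairing_duplex(SPIKE_IN_A, SPIKE_IN_C)
        assert d.n_pairs == 30
        assert len(d.loops) == 1
        loop = d.loops[0]
        assert loop.kind == "bulge"
        assert loop.bulge_strand == "B"
        assert loop.len_b == 1

    def test_a_d_single_internal_loop(self):
        d = max_pairing_duplex(SPIKE_IN_A, SPIKE_IN_D)
        assert d.n_pairs == 29
        assert len(d.loops) == 1
        assert d.loops[0].kind == "internal"
        assert (d.loops[0].len_a, d.loops[0].len_b) == (1, 1)

    def test_energy_ranks_perfect_below_defective(self, model):
        e_ab = hybrid_mfe(SPIKE_IN_A, SPIKE_IN_B, model).energy
        e_ac = hybrid_mfe(SPIKE_IN_A, SPIKE_IN_C, model).energy
        assert e_ab < e_ac
        assert hybrid_mfe(SPIKE_IN_A, SPIKE_IN_B, model).longest_helix == 30


class TestLongestComplementaryRun:
    def test_oligo_pair_runs(self):
        assert longest_complementary_run(SPIKE_IN_A, SPIKE_IN_B)[0] == 30
        assert longest_complementary_run("AAAA", "AAAA")[0] == 0
        assert longest_complementary_run("GGGG", "CCCC") == (4, 0, 0)

    def test_matches_lcs_oracle_on_random_pairs(self, rng):
        for _ in range(300):
            a = random_rna(rng, int(rng.integers(3, 30)))
            b = random_rna(rng, int(rng.integers(3, 30)))
            expected = oracles.longest_common_substring(a, oracles.revcomp(b))
            assert longest_complementary_run(a, b)[0] == expected

    def test_coordinates_name_a_real_block(self, rng):
        for _ in range(50):
            a = random_rna(rng, 25)
            b = random_rna(rng, 25)
            length, sa, sb = longest_complementary_run(a, b)
            if length == 0:
                continue
            block_a = a[sa : sa + length]
            block_b = b[sb : sb + length]
            assert oracles.revcomp(block_b) == block_a


class TestMaxPairing:
    def test_full_complement_pairs_everything(self, rng):
        for _ in range(20):
            a = random_rna(rng, int(rng.integers(2, 12)))
            d = max_pairing_duplex(a, oracles.revcomp(a))
            assert d.n_pairs == len(a)
            assert d.loops == ()

    def test_pair_count_monotone_under_extension(self, rng):
        for _ in range(30):
            a = random_rna(rng, 10)
            b = random_rna(rng, 10)
            base = max_pairing_duplex(a, b).n_pairs
            assert max_pairing_duplex(a + random_rna(rng, 1), b).n_pairs >= base
            assert max_pairing_duplex(a, b + random_rna(rng, 1)).n_pairs >= base

    def test_swap_symmetry(self, rng):
        for _ in range(20):
            a = random_rna(rng, int(rng.integers(4, 15)))
            b = random_rna(rng, int(rng.integers(4, 15)))
            d_ab = max_pairing_duplex(a, b)
            d_ba = max_pairing_duplex(b, a)
            assert d_ab.n_pairs == d_ba.n_pairs
            assert len(d_ab.loops) == len(d_ba.loops)


class TestHybridMfe:
    def test_closed_form_triplet(self, model):
        d = hybrid_mfe("GGG", "CCC", model)
        expected = model.helix_init + 2 * model.stack(("G", "C"), ("G", "C"))
        assert d.n_pairs == 3
        assert d.energy == pytest.approx(expected)

    def test_exact_reverse_complement_fully_paired(self, model, rng):
        for _ in range(10):
            a = random_rna(rng, int(rng.integers(4, 12)))
            d = hybrid_mfe(a, oracles.revcomp(a), model)
            assert d.n_pairs == len(a)

    def test_no_admissible_pairs(self, model):
        d = hybrid_mfe("AAAA", "AAAA", model)
        assert d.pairs == ()
        assert d.energy == 0.0

    def test_matches_enumeration_oracle(self, model, rng):
        for _ in range(60):
            a = random_rna(rng, int(rng.integers(2, 9)))
            b = random_rna(rng, int(rng.integers(2, 9)))
            expected = oracles.oracle_mfe(a, b, model)
            got = hybrid_mfe(a, b, model)
            if expected is None:
                assert got.pairs == ()
            else:
                assert got.energy == pytest.approx(expected, abs=1e-6)

    def test_swap_symmetry(self, model, rng):
        for _ in range(20):
            a = random_rna(rng, int(rng.integers(3, 10)))
            b = random_rna(rng, int(rng.integers(3, 10)))
            ea = hybrid_mfe(a, b, model).energy
            eb = hybrid_mfe(b, a, model).energy
            assert ea == pytest.approx(eb, abs=1e-6)


class TestSuboptimal:
    def test_window_zero_contains_only_mfe_ties(self, model, rng):
        for _ in range(20):
            a = random_rna(rng, 8)
            b = random_rna(rng, 8)
            subs = suboptimal_duplexes(a, b, model, window_kcal=0.0)
            if not subs:
                continue
            mfe = subs[0].energy
            assert all(s.energy == pytest.approx(mfe, abs=1e-6) for s in subs)

    def test_gggg_cccc_counts_match_bruteforce(self, model):
        subs = suboptimal_duplexes("GGGG", "CCCC", model, window_kcal=50.0)
        expected = oracles.oracle_suboptimal("GGGG", "CCCC", model, 50.0)
        assert len(subs) == len(expected)
        got = impl_footprints(subs, 4)
        for fp, e in expected.items():
            assert got[fp] == pytest.approx(e, abs=1e-6)

    def test_no_admissible_pairs_gives_empty(self, model):
        assert suboptimal_duplexes("AAA", "AAA", model) == []

    def test_matches_enumeration_oracle(self, model, rng):
        for _ in range(40):
            a = random_rna(rng, int(rng.integers(2, 9)))
            b = random_rna(rng, int(rng.integers(2, 9)))
            expected = oracles.oracle_suboptimal(a, b, model, 2.0)
            got = impl_footprints(suboptimal_duplexes(a, b, model, 2.0), len(b))
            assert set(got) == set(expected)
            for fp in expected:
                assert got[fp] == pytest.approx(expected[fp], abs=1e-6)

    def test_sorted_by_energy_with_mfe_first(self, model):
        subs = suboptimal_duplexes("GGCGC", "GCGCC", model, window_kcal=3.0)
        energies = [s.energy for s in subs]
        assert energies == sorted(energies)


class TestInteractionScore:
    def test_sum_over_nonoverlapping_sites(self, model, rng):
        # independent greedy re-implementation of the site reduction
        for _ in range(10):
            a = random_rna(rng, 8)
            b = random_rna(rng, 8)
            subs = suboptimal_duplexes(a, b, model, 2.0)
            kept = []
            for s in subs:
                i0, i1, j0, j1 = s.footprint
                if not any(
                    (i0 <= k[1] and k[0] <= i1) or (j0 <= k[3] and k[2] <= j1)
                    for k in kept
                ):
                    kept.append((i0, i1, j0, j1, s.energy))
            assert interaction_score(a, b, model, 2.0) == pytest.approx(
                sum(k[4] for k in kept), abs=1e-6
            )

    def test_planted_site_scores_deeper_than_random_target(self, model, rng):
        read = random_rna(rng, 20)
        random_target = random_rna(rng, 200)
        planted = random_rna(rng, 200)
        planted = planted[:90] + oracles.revcomp(read) + planted[110:]
        assert interaction_score(read, planted, model) < interaction_score(
            read, random_target, model
        )

    def test_empty_list_scores_zero(self, model):
        assert interaction_score("AAA", "AAA", model) == 0.0

    def test_score_at_most_mfe_when_all_terms_negative(self, model, rng):
        # when even the shallowest structure in the window is stabilizing,
        # summing can only deepen the score below the MFE
        hits = 0
        for _ in range(40):
            a = random_rna(rng, 15)
            b = random_rna(rng, 15)
            subs = suboptimal_duplexes(a, b, model, 2.0)
            if subs and subs[-1].energy < 0:
                hits += 1
                assert interaction_score(a, b, model, 2.0) <= subs[0].energy + 1e-9
        assert hits > 5


class TestDuplexStructure:
    def test_helix_lengths_sum_to_pairs(self):
        d = DuplexStructure(((0, 9), (1, 8), (3, 6), (4, 5)), 10, 10)
        assert sum(h[2] for h in d.helices) == d.n_pairs
        assert len(d.helices) == 2
        assert d.loops[0].kind == "internal"

    def test_antiparallel_ordering_enforced(self):
        with pytest.raises(ValueError):
            DuplexStructure(((0, 5), (1, 6)), 10, 10)

    def test_two_line_rendering_marks_paired_bases(self):
        d = max_pairing_duplex("GGG", "CCC")
        text = d.to_lines("GGG", "CCC")
        assert "GGG" in text and "CCC" in text
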