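import numpy as np
import pytest

from duplexseq.mapping import (
    CoverageProfile,
    Match,
    TranscriptIndex,
    class_enrichment,
    coverage_profiles,
    gene_class_coverage,
    map_read,
    map_reads,
    normalize_profile,
)

from conftest import make_read, make_transcript, random_rna


@pytest.fixture()
def toy_index(rng):
    t1 = make_transcript("t1", random_rna(rng, 100))
    t2 = make_transcript("t2", random_rna(rng, 80))
    return TranscriptIndex([t1, t2]), t1, t2


class TestMapRead:
    def test_unique_occurrence_weight_one(self, toy_index):
        index, t1, _ = toy_index
        read = make_read("r", t1.seq[10:32])
        matches = map_read(read, index)
        assert matches == [Match("r", "t1", 10, 32, 1.0)]

    def test_four_occurrences_across_two_transcripts(self):
        motif = "ACGGUCAAGGUCCAAGGAUACG"
        t1 = make_transcript("t1", motif + "AAAA" + motif)
        t2 = make_transcript("t2", "CCCC" + motif + "GGGG" + motif)
        index = TranscriptIndex([t1, t2])
        matches = map_read(make_read("r", motif), index)
        assert len(matches) == 4
        assert all(m.weight == pytest.approx(0.25) for m in matches)
        assert sum(m.weight for m in matches) == pytest.approx(1.0)

    def test_no_match_empty(self, toy_index):
        index, _, _ = toy_index
        assert map_read(make_read("r", "A" * 25), index) == []

    def test_order_invariance(self, rng):
        t1 = make_transcript("t1", random_rna(rng, 60))
        t2 = make_transcript("t2", random_rna(rng, 60))
        read = make_read("r", t2.seq[5:30])
        m_fwd = map_read(read, TranscriptIndex([t1, t2]))
        m_rev = map_read(read, TranscriptIndex([t2, t1]))
        assert m_fwd == m_rev


class TestCoverage:
    def test_single_match_mass_conserved(self, toy_index):
        index, t1, t2 = toy_index
        matches = [Match("r", "t1", 0, 22, 1.0)]
        profiles = coverage_profiles(matches, index.transcripts)
        assert profiles["t1"].cov.sum() == pytest.approx(22.0)
        assert profiles["t2"].cov.sum() == 0.0

    def test_overlapping_half_weights_add(self, toy_index):
        index, t1, _ = toy_index
        matches = [Match("a", "t1", 0, 20, 0.5), Match("b", "t1", 10, 30, 0.5)]
        cov = coverage_profiles(matches, index.transcripts)["t1"].cov
        assert np.allclose(cov[10:20], 1.0)
        assert np.allclose(cov[:10], 0.5)

    def test_out_of_range_raises(self, toy_index):
        index, _, _ = toy_index
        with pytest.raises(ValueError):
            coverage_profiles([Match("r", "t2", 70, 95, 1.0)], index.transcripts)

    def test_total_mass_counts_each_mapped_read_once(self, rng):
        transcripts = [
            make_transcript("t1", random_rna(rng, 120)),
            make_transcript("t2", random_rna(rng, 120)),
        ]
        index = TranscriptIndex(transcripts)
        reads = [make_read(f"r{i}", transcripts[i % 2].seq[i : i + 20]) for i in range(10)]
        matches = map_reads(reads, index)
        profiles = coverage_profiles(matches, transcripts)
        total = sum(p.cov.sum() for p in profiles.values())
        mapped = [r for r in reads if map_read(r, index)]
        assert total == pytest.approx(sum(len(r) for r in mapped))


class TestNormalize:
    def test_divides_by_max(self):
        prof = CoverageProfile("t", np.array([2.0, 4.0, 1.0]))
        assert np.allclose(normalize_profile(prof).cov, [0.5, 1.0, 0.25])

    def test_zero_profile_unchanged(self):
        prof = CoverageProfile("t", np.zeros(5))
        assert normalize_profile(prof) is prof

    def test_peak_is_one(self, rng):
        prof = CoverageProfile("t", rng.random(50) + 0.1)
        assert normalize_profile(prof).cov.max() == pytest.approx(1.0)


class TestHierarchy:
    def test_single_gene_passthrough(self):
        t = make_transcript("t1", "ACGUACGUAC", gene="g1", gene_class="mRNA")
        profiles = {"t1": CoverageProfile("t1", np.full(10, 0.4))}
        assert gene_class_coverage(profiles, [t]) == {"mRNA": pytest.approx(0.4)}

    def test_gene_level_average_not_transcript_weighted(self):
        # gene g1 has two transcripts (means 0.1 and 0.3 -> gene mean 0.2),
        # gene g2 has one transcript (mean 0.6); class mean must be 0.4
        ts = [
            make_transcript("t1", "A" * 10, gene="g1"),
            make_transcript("t2", "A" * 10, gene="g1"),
            make_transcript("t3", "A" * 10, gene="g2"),
        ]
        profiles = {
            "t1": CoverageProfile("t1", np.full(10, 0.1)),
            "t2": CoverageProfile("t2", np.full(10, 0.3)),
            "t3": CoverageProfile("t3", np.full(10, 0.6)),
        }
        assert gene_class_coverage(profiles, ts)["mRNA"] == pytest.approx(0.4)

    def test_output_classes_subset_of_annotation(self, rng):
        ts = [
            make_transcript("t1", random_rna(rng, 20), gene_class="tRNA"),
            make_transcript("t2", random_rna(rng, 20), gene_class="rRNA"),
        ]
        profiles = coverage_profiles([], ts)
        out = gene_class_coverage(profiles, ts)
        assert set(out) == {"tRNA", "rRNA"}


class TestClassEnrichment:
    def test_simple_ratio(self):
        assert class_enrichment({"rRNA": 2.0}, {"rRNA": 4.0}) == {"rRNA": 0.5}

    def test_identity(self):
        cov = {"mRNA": 0.3, "tRNA": 0.7}
        assert class_enrichment(cov, cov) == {"mRNA": 1.0, "tRNA": 1.0}

    def test_zero_denominator_flagged_nan(self):
        out = class_enrichment({"mRNA": 1.0}, {"mRNA": 0.0})
        assert np.isnan(out["mRNA"])
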