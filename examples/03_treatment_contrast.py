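"""Native vs protein-removed treatment contrast on a simulated experiment.

Simulates the same cell's RNA pool under two treatments at a matched seed,
then runs the core readouts: the all-vs-all longest-helix scan (with a
shuffled control) and the per-gene-class coverage enrichment between the
treatments.
"""

from duplexseq import (
    TranscriptIndex,
    all_vs_all_scan,
    class_enrichment,
    coverage_profiles,
    gene_class_coverage,
    length_filter,
    map_reads,
    scan_summary,
    shuffled_control_scan,
)
from duplexseq.simulate import SimConfig, simulate_library

SEED = 7
summaries = {}
class_cov = {}
for treatment in ("native", "protein_removed"):
    config = SimConfig(treatment=treatment, master_seed=SEED)
    txome, reads, truth = simulate_library(config)
    kept = length_filter(reads)  # the protocol's >18 nt filter

    profile = all_vs_all_scan(kept, engine="energy")
    control = shuffled_control_scan(kept, engine="energy", seed=SEED)
    median, maximum, _ = scan_summary(profile)
    s_median, _, _ = scan_summary(control)
    print(
        f"{treatment:>15}: {len(kept):3d} reads; longest-helix median "
        f"{median:4.1f} bp (shuffled {s_median:4.1f}), max {maximum} bp"
    )

    matches = map_reads(kept, TranscriptIndex(txome.transcripts))
    profiles = coverage_profiles(matches, txome.transcripts)
    class_cov[treatment] = gene_class_coverage(profiles, txome.transcripts)

ratios = class_enrichment(class_cov["protein_removed"], class_cov["native"])
print("\ncoverage enrichment, protein-removed / native:")
for cls, ratio in sorted(ratios.items()):
    print(f"  {cls:<11} {ratio:5.2f}")
# Removing proteins lets planted duplexes reanneal: the helix median jumps
# from single digits to ~30 bp, and every class except the rRNA-like one
# (whose native reads come from heavy protein protection) is enriched.
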