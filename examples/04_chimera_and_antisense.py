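"""Chimeric-read search and sense/antisense contingency enrichment.

Chimeras - reads whose 5' and 3' ends match two different transcripts for
at least 18 nt each - would be evidence of endogenous ligation; the
digestion simulator produces none, so detections on constructed positives
are shown instead.  The contingency analysis asks whether genes with an
opposite-strand genomic overlap are likelier to carry read matches.
"""

from duplexseq import (
    TranscriptIndex,
    aggregate_factors,
    annotate_antisense_overlap,
    build_contingency,
    enrichment_factor,
    find_chimeras,
    gene_match_flags,
    length_filter,
    map_reads,
)
from duplexseq.seqio import ReadRecord
from duplexseq.simulate import SimConfig, simulate_contingency_datasets, simulate_library

config = SimConfig(treatment="protein_removed", master_seed=3)
txome, reads, truth = simulate_library(config)
kept = length_filter(reads)
index = TranscriptIndex(txome.transcripts)

calls = find_chimeras(kept, index)
print(f"chimera calls on the digested library: {len(calls)}")

tx_a, tx_b = txome.transcripts[0], txome.transcripts[1]
constructed = ReadRecord("ligation_product", tx_a.seq[:20] + tx_b.seq[30:50])
for call in find_chimeras(kept + [constructed], index):
    print(
        f"  {call.read_id}: 5' {call.l5} nt on {call.five_prime[0]}, "
        f"3' {call.l3} nt on {call.three_prime[0]}, gap {call.gap}"
    )

overlap = annotate_antisense_overlap(txome.transcripts)
matches = map_reads(kept, index)
table = build_contingency(overlap, gene_match_flags(matches, txome.transcripts), "demo")
print(
    f"\ncontingency a,b,c,d = {table.a},{table.b},{table.c},{table.d}; "
    f"enrichment factor (relative risk) = {enrichment_factor(table):.2f}"
)

tables = simulate_contingency_datasets(n_datasets=13, relative_risk=2.4, seed=1)
mean, sd, n_def, _ = aggregate_factors(tables)
print(f"13 simulated datasets with planted RR 2.4 -> {mean:.2f} +/- {sd:.2f}")
# Antisense-overlapping genes carry planted duplexes, so they attract read
# matches far more often than non-overlapping genes; across 13 replicate
# datasets the planted relative risk is recovered within sampling error.
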