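"""Structural classification and digestion of the spike-in control oligos.

The three annealed constructs - perfect 30-bp duplex (A/B), single-nt
bulge (A/C) and 1x1 internal loop (A/D) - are the controls used to tune a
single-strand-specific RNase digestion: only the perfect duplex should
survive, with its 3' overhangs clipped off.
"""

from duplexseq import max_pairing_duplex
from duplexseq.controls import SPIKE_IN_A, SPIKE_IN_OLIGOS
from duplexseq.simulate import (
    SimConfig,
    generate_transcriptome,
    plant_duplexes,
    simulate_digestion,
)

for name in "BCD":
    duplex = max_pairing_duplex(SPIKE_IN_A, SPIKE_IN_OLIGOS[name])
    loops = ", ".join(f"{lp.kind}({lp.len_a}x{lp.len_b})" for lp in duplex.loops) or "none"
    print(
        f"A/{name}: {duplex.n_pairs} pairs, longest helix {duplex.longest_helix} bp, "
        f"loops {loops}, 3' overhangs {duplex.overhang3_a}/{duplex.overhang3_b} nt"
    )

# digest the three constructs at full nuclease efficiency, no protein
config = SimConfig(
    n_genes={c: 0 for c in ("rRNA", "mRNA", "tRNA", "lincRNA", "pseudogene", "other")},
    antisense_pair_fraction=0.0,
    n_planted_duplexes=0,
    include_spike_ins=True,
    cleavage_prob=1.0,
    treatment="protein_removed",
)
txome = generate_transcriptome(config, 1)
txome, molecules, duplexes = plant_duplexes(txome, config, 2)
fragments = simulate_digestion(molecules, duplexes, config, 3)
print("\nafter RNase A/T1 digestion (size selection 18-50 nt):")
for f in fragments:
    status = "kept" if f.survived else "lost"
    print(f"  {f.fragment_id:<22} {len(f):>2} nt  defect={f.defect:<9} {status}")
# Only the two 30-nt strands of the perfect duplex survive: the bulge and
# the mismatch let the nuclease sever the helix into sub-18-bp pieces.
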