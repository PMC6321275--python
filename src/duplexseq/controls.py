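"""Control sequences used throughout the package and its tests.

The four spike-in oligos are GFP-derived 35/36-mers used to monitor the
single-strand-specific digestion: A/B anneal into a 30-bp perfect duplex
with a 5-nt overhang at both 3' ends, A/C contains a single-nucleotide
bulge (C carries one extra U), and A/D contains a 1x1 internal loop (D
carries a single substitution).  ``RRNA_ES27_READ`` is the extremely
GC-rich 22-nt fragment of the human 28S rRNA expansion segment ES27L that
dominates gel-extracted libraries in this protocol.
"""

SPIKE_IN_A = "AGCAGAACACCCCCAUCGGCGACGGCCCCGUGCUG"
SPIKE_IN_B = "CGGGGCCGUCGCCGAUGGGGGUGUUCUGCUGCUGC"
SPIKE_IN_C = "CGGGGCCGUCGCCGAUUGGGGGUGUUCUGCUGCUGC"
SPIKE_IN_D = "CGGGGCCGUCGCCGAUAGGGGUGUUCUGCUGCUGC"

SPIKE_IN_OLIGOS = {
    "A": SPIKE_IN_A,
    "B": SPIKE_IN_B,
    "C": SPIKE_IN_C,
    "D": SPIKE_IN_D,
}

RRNA_ES27_READ = "CGGGCGGCGGCGGUCGGCGGGC"
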