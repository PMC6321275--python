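# Methods

## The assay being modeled

A single-strand-specific ribonuclease cocktail (RNase A cleaves 3′ of
pyrimidines, RNase T1 3′ of guanosine; base-paired regions are refractory)
is applied to cellular RNA under three treatments: the native lysate,
total RNA after protein removal and heat/formamide reannealing, and the
same after rRNA depletion. Surviving duplexes of 18–50 bp are gel-selected,
denatured and sequenced strand-wise. The computational questions this
package answers are: which duplexes could the reads have come from, are
they longer or more frequent than chance, which gene classes gain or lose
material between treatments, and is duplex formation associated with
cis-sense/antisense genomic overlap.

## Duplex prediction

Hybrids between two strands are antiparallel, pseudoknot-free and purely
intermolecular: pair indices strictly increase along strand A and strictly
decrease along strand B, intramolecular pairs are never formed. Three
engines share this structure space:

* **Maximal pairing** (`max_pairing_duplex`): dynamic program maximizing
  the lexicographic objective (number of pairs, −number of loops) with a
  running prefix-maximum, O(nm). Terminal unpaired runs are free
  (overhangs, not loops). Used for structural classification where no
  energetics are wanted.
* **Perfect-run statistic** (`longest_complementary_run`): longest
  contiguous antiparallel block of perfect complementarity; equal, by
  construction, to the longest common substring of A and the reverse
  complement of B when wobble pairs are excluded (they are by default here,
  since the statistic is about perfect reverse-complementary regions).
* **Energy minimization** (`hybrid_mfe`, `suboptimal_duplexes`): a
  nearest-neighbor model with Watson–Crick stacking increments from the
  standard 37 °C duplex parameter set and literature-style G·U values,
  shipped as a TSV asset (`data/stack_dg37.tsv`) closed under the physical
  strand-exchange symmetry. Bulges and internal loops carry affine
  penalties (bulge: 3.8 + 0.4·(n−1); internal: 1.7 + 0.35·(s−2) kcal/mol);
  one duplex-initiation term (+4.09); no dangling ends, coaxial stacking
  or terminal-AU terms. Unpaired runs longer than `max_loop` (15)
  terminate a duplex. The forward DP is exact over this model; the
  energies are approximate thermodynamics, but every statistic downstream
  uses relative energies only, and the table is swappable.

Suboptimal enumeration is exact (depth-first traceback with the DP matrix
as an admissible completion bound) and reports one representative — the
best-energy structure — per distinct pair of paired intervals
("footprint"). Ties everywhere break toward lexicographically smallest
coordinates, so results are deterministic. For short sequences the whole
machinery is tested against brute-force enumeration of all admissible pair
chains.

## The interaction score and its z-score

The score of a pair is the summed energy of the MFE structure and the
suboptimal structures within 2 kcal/mol. One refinement proved necessary:
summing **every** distinct-footprint structure lets weak interactions
outscore strong ones, because a shallow MFE admits a combinatorial cloud
of within-window variants (dropping a weak terminal stack costs < 2
kcal/mol, so subsets proliferate), whereas a single deep site has few.
`interaction_score` therefore first reduces the window set to greedy
non-overlapping site representatives (best energy first; a structure is
kept only if its paired interval on each strand is disjoint from all kept
ones) and sums those. This mirrors how hybridization tools report
alternative binding sites, makes a planted perfect site reliably outscore
random targets, and leaves each site counted exactly once.
`suboptimal_duplexes` itself keeps full footprint-level multiplicity.

Significance: the read is shuffled n = 20 times (mononucleotide by
default; an Euler-path dinucleotide shuffle is available because
extremely GC-rich reads make composition-only nulls weak), the target
stays fixed, and z = (S_native − mean)/sd with the sample (n−1) standard
deviation — conventional at n = 20 and documented rather than assumed.
sd = 0 yields a flagged NaN, never a crash or a selection. Transcripts
with z strictly below −3 are called over-represented; the cutoff is a
parameter. Seeds fan out through a splittable scheme (`child_seeds`) so
increasing n never perturbs earlier draws.

## All-versus-all scan

Reads are grouped by exact length (this both follows the assay's design —
duplex strands co-migrate — and bounds the quadratic cost); each unordered
pair within a group is folded and each read records the longest helix of
its best partner. Identical sequences are collapsed before prediction and
re-expanded after (toggleable); a sequence present as two or more reads is
also scored against itself, since two identical molecules can duplex,
while a single read is never paired with its own record. The planned pair
count Σ_g C(|g|,2) is computed and logged before scanning. The default
engine reads helix length off the MFE structure; `max_pairing` mode is the
fast, string-exactly-checkable alternative and equals
`longest_complementary_run` pair-by-pair. Summaries are the median
(midpoint convention), maximum, and an integer histogram. The shuffled
control re-runs the scan after per-read composition-preserving shuffles.

## Mapping, coverage, enrichment

Matching is full-length exact substring occurrence on the transcript's
forward strand (antisense relationships live entirely in the genomic
interval annotations, keeping strand semantics in one place); a read with
k occurrences contributes 1/k to each, so each mapped read carries unit
mass. Coverage adds match weights per nucleotide; normalization divides by
the profile maximum (all-zero profiles pass through). Class summaries use
a strict three-level hierarchy — position mean per transcript, transcript
mean per gene, gene mean per class — so a gene with many transcript
isoforms does not dominate its class. Enrichment between treatments is
the per-class ratio, with zero denominators flagged NaN rather than
infinite.

## Chimera detection

A call needs the read's maximal exact prefix and suffix matches to reach
18 nt (inclusive — a distinct threshold from the strict >18-nt read-length
filter), land on different transcripts, not overlap on the read, with no
full-length match anywhere and no single transcript containing both
segments (the intra-transcript explanation, interpreted as containment
anywhere on the transcript). When maximal segments overlap only because a
junction base matches by chance, they are trimmed back (5′ side first)
while both remain at the threshold; without this, a quarter of genuine
junctions would be lost to a single chance base. Ties across transcripts
produce one call per combination, flagged ambiguous.

## Antisense contingency

The unit of analysis is the gene. A gene is overlap-positive if any of
its transcripts' intervals intersects (≥1 bp, same chromosome, 0-based
half-open — abutting intervals do not overlap) a transcript of a
*different* gene on the opposite strand; it is match-positive if any read
maps to any of its transcripts. The enrichment factor is the relative
risk (a/(a+b))/(c/(c+d)) — chosen over the odds ratio because the claim
being quantified is "more likely to have matches" — undefined (NaN) when
c = 0. Across datasets the factors aggregate as mean ± sample sd with
undefined factors skipped and counted.

## The simulator: what it emulates and what it does not

`generate_transcriptome` draws a class-structured pool (defaults: 2
rRNA-like genes of 1.2–1.8 kb at GC 0.80; 14 mRNA of 0.3–0.7 kb; 6 tRNA of
70–90 nt; 6 lincRNA; 4 pseudogenes; 2 other; one transcript per gene) with
non-overlapping genomic placements, then attaches antisense partner genes
to half the mRNAs: an opposite-strand interval inside the partner's span
plus an embedded reverse-complement window, so sequence-level duplex
potential and interval-level overlap coincide. `plant_duplexes` adds 20
more complementary windows (18–40 bp; 70% perfect, 15% single bulge, 15%
1×1 mismatch) between random transcript pairs, splicing the window into
the partner's sequence so digested reads still map exactly, and
instantiates 3 molecule copies per transcript. The printed control oligos
(A/B perfect 30 bp with 5-nt 3′ overhangs, A/C bulged, A/D mismatched) can
be spiked in.

Digestion semantics (the deliberate simplifications are here):

* Cleavage is modeled as **excision** of an exposed cut base (C, U, G;
  configurable) with probability `cleavage_prob` per base, rather than a
  single 3′ nick. This yields clean helix boundaries (the perfect spike-in
  survives as exactly 30-nt strands) at the cost of ignoring the one
  terminal nucleotide a pure endonuclease would leave.
* A cleaved **defect junction** (bulge or mismatch inside a formed duplex)
  severs the complex into its flanking sub-duplexes, cutting both
  backbones — strand breathing at the defect exposes both strands locally.
  Hence A/C splits 16 + 14 and A/D 16 + 13, and neither yields a fragment
  ≥18 nt under full digestion, while a junction that escapes cleavage
  leaves the whole defective duplex intact (partial survival under native
  conditions).
* **Native treatment**: protein binding blocks each planted duplex from
  forming with probability `native_pairing_block` (0.85); a blocked
  region, and a random window on unplanted molecules, is shielded from
  digestion with the per-class `protein_occlusion` probability (0.9 for
  the rRNA-like class — ribosomal proteins — 0.2 elsewhere); digestion
  efficiency drops to `native_cleavage_prob` (0.85). Blocking and
  shielding are decoupled on purpose: proteins prevent pairing far more
  reliably than they protect against nucleases, and only that decoupling
  reproduces both headline contrasts at once (few long helices in native
  scans *and* non-rRNA coverage gain upon protein removal).
* **Protein-removed** reanneals every planted region regardless of
  occlusion; **ribo-removed** additionally discards rRNA-class molecules.
* Duplex-containing pieces are trimmed to their paired span (accessible
  tails carry cut sites and breathe); both strands of a surviving complex
  are emitted as independent reads with uniform Phred-40 qualities, after
  an 18–50 size selection on the complex. RNase leaves a 3′ phosphate;
  the flag is recorded on every cut-derived fragment but has no
  downstream effect, as dephosphorylation precedes ligation in the
  protocol.

Not modeled: sequencing errors, PCR duplication, adapters, gel-mobility
details, intramolecular secondary structure (so "stochastic
self-complements" in a negative control arise only from literal sequence
repeats), and real cellular abundance distributions. Passing tests
therefore demonstrate that the pipeline's inferences are correct *given*
the generative assumptions — treatment contrasts, planted-duplex recovery,
enrichment directions — not that the defaults quantitatively match any
particular cell line. The default problem sizes (≈ 40 genes, ≈ 50–130
surviving reads per library) are the package's chosen desk scale: large
enough for every direction check to be stable across seeds, small enough
that the full suite runs in seconds.

## Numerical and degenerate-input conventions

Energies are float64 throughout; structure equality in tests uses 1e-6
tolerances against brute-force enumeration. Empty inputs return empty
outputs (empty FASTQ → empty list; no admissible pairs → empty structure
with energy 0; empty suboptimal list → score 0). The quality trimmer cuts
at the first sub-threshold base inside the first sliding window whose mean
falls below the threshold (window 10, Q20 defaults; both configurable
because the upstream trimmer's defaults are not printed anywhere
authoritative). The read-length filter is strictly greater-than 18; the
chimera segment threshold is ≥18; the two are deliberately distinct
configuration keys.

## Known limitations

The G·U stacking values are literature-style estimates, not a certified
parameter set; swap the TSV for calibrated work. The energy DP costs
O(n·m·max_loop²) per pair, fine for reads and few-kb transcripts but not
for chromosome-scale targets. The all-vs-all scan is quadratic per length
group; deduplication mitigates but does not remove this. The enrichment
factor is reported without a significance test, matching the analysis it
implements. Dataset-scale medians from real libraries (tens of thousands
of reads) are outside the default desk scale; the pipeline accepts such
libraries but runtime grows accordingly.
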