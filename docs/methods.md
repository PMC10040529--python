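# Methods

## The screen

`pancooc` tests, for every gene family in a small pan-genome, whether the
family's per-genome abundance tracks a quantitative phenotype. The statistic
is the sample Pearson correlation r between the family's copy-count vector
x (one entry per genome) and the phenotype vector y (maximum NaCl tolerated,
% w/v). The n−1 normalisations cancel in the ratio, so the sample and
population forms coincide; values are clamped to [−1, 1] against floating
rounding. Families whose x is constant across genomes (the core genome)
have zero variance and no defined correlation: they are flagged undefined
and reported in a separate table, never silently dropped and never treated
as zero.

Screening applies a strict cut r > threshold (default 0.8) on the
*unrounded* value; the results table prints r at two decimals, rounded
half-away-from-zero so that ties resolve identically across platforms
(0.815 → 0.82). Output is ordered by printed value descending, then by
cluster id. Only positive exceedances pass by default — the screen looks
for families whose *presence* accompanies tolerance; `signed=False`
(`--absolute`) screens on |r| instead and surfaces anti-correlated
families. No multiple-testing correction is applied: the method is a raw
threshold screen generating hypotheses, not a calibrated test. A family
passing at r > 0.8 with n = 6 genomes is suggestive, not significant.

### Copy counts versus presence/absence

The default abundance is the integer copy count, with presence/absence
binarisation available as a mode. The choice is forced by arithmetic: with
y = (10, 9, 9, 5, 4, 3), exhaustive enumeration over all 63 binary patterns
(`enumerate_patterns`) shows the attainable two-decimal values do not
include 0.84, while count vectors such as (1, 1, 2, 0, 0, 0) reach it.
The enumeration table doubles as a verification oracle: for a given y it
lists every abundance pattern (up to a copy bound) with its r, so one can
ask which patterns could explain a reported value. It is exact, guarded to
n ≤ 8 genomes and counts ≤ 4.

## Gene families

Proteins are compared by Smith–Waterman local alignment with affine gaps
(via Biopython's `PairwiseAligner`), BLOSUM62, gap open 11, gap extend 1 —
blastp's defaults, under the convention that a gap of length L costs
11 + L·1. Scores are floored at 0 (no positive-scoring local alignment).
The distance is the score-normalised form

    d(a, b) = 1 − 2·S(a, b) / (S(a, a) + S(b, b))

clamped to [0, 1]: 0 for identical sequences, 1 for unalignable ones.
Families are single-linkage clusters: connected components of the graph
whose edges are pairs with d strictly below the threshold (default 0.75).
Strict inequality makes threshold = 1.0 mean "merge everything not at
maximal distance". Cluster names `Cluster_1…K` are assigned by ascending
order of each cluster's lexicographically smallest member id, so the
partition *and* the naming are invariant under input permutation. An
optional k-mer prefilter (default k = 4) assigns d = 1 without aligning to
pairs sharing no exact k-mer; it only skips pairs far above the threshold,
and tests assert the clustering is identical with it on or off.

The O(n²) all-pairs cost is acceptable at the intended scale (hundreds to
a few thousand proteins); the package deliberately avoids heuristic seeded
search — determinism and auditability over speed.

## ORF prediction

Six-frame scanning with the standard genetic code: within each frame, each
maximal stop-to-stop segment contributes at most one ORF, opened at the
segment's first start codon (default {ATG}; GTG/TTG can be added) and kept
if the translated product has ≥ 100 residues (default) and a terminal stop
(required by default). Coordinates are 1-based inclusive on the forward
strand regardless of coding strand, GFF3-style, and the reported span
includes the stop codon. Ambiguous bases are rejected rather than skipped —
on synthetic input they always indicate a bug. The 100-residue floor and
ATG-only starts are conventional choices for a transparent, dependency-free
caller; the pipeline also accepts pre-predicted per-strain protein FASTA
and skips this stage entirely.

## Synthetic data

The generator emulates the screen's study design: six strains with
phenotype (10, 9, 9, 5, 4, 3) % w/v NaCl in decreasing order, and a family
panel of five planted patterns — (1,1,1,0,0,0) → r = 0.97, (1,1,1,1,0,0) →
0.81, (1,1,2,0,0,0) → 0.84, a constant core family (undefined), an
anti-correlated (0,0,0,1,1,1) → −0.97 — plus 30 background families with
random copy counts in {0, 1, 2} per strain (P = 0.35/0.50/0.15, redrawn if
all-zero). Defaults: 120-residue proteins, 5 % per-residue within-family
substitution (substituted positions always change to a different residue),
~120 nt spacers, one contig per strain. The panel size is chosen for
desk-scale runtime (a full pipeline run takes ~1–2 s); nothing in the
method depends on it. The truth ledger records each family's copy counts
and its expected co-occurrence computed *by the same statistic the screen
uses*, so end-to-end recovery is checkable exactly.

Expected within-family divergence is ~2 × 5 % = 10 % of residues between
two copies, giving d ≈ 0.1–0.2 — far below the 0.75 clustering threshold —
while independent random proteins land at d > 0.9; both margins are
asserted empirically on seeded fixtures.

### Exact gene recovery by construction

The recovery contract — the ORF caller finds exactly the planted genes,
nothing more, nothing less — is engineered, not hoped for:

* **Spacers.** Intergenic DNA interleaves random chunks (≤ 60 nt) with the
  guard block `TTAATTAATTAA`, which equals its own reverse complement and
  contains a stop codon in all six frames. Spacers begin and end with a
  guard, so no ORF can cross a gene boundary, and the codon immediately
  upstream of a gene's ATG, in the gene's frame, is a stop on both strands.
* **Codon choice.** Reverse translation uses one fixed codon per residue
  (byte-stable output; a seeded-uniform table would work but adds nothing).
  The default table was selected by a small combinatorial search to
  maximise the minimum stop-codon density over the five non-coding frames
  of a random coding sequence (TTA/TCA read as stops on the reverse strand;
  junction triplets hit stops with probability ≈ 0.07–0.11 per codon), so
  "shadow" ORFs ≥ 100 residues inside a gene are rare.
* **Validation.** Rare is not never: every prototype and every mutated copy
  is validated by scanning its guard-flanked CDS with the ORF caller, and
  redrawn from the same deterministic random stream if any ORF other than
  the gene itself appears (in practice a redraw is needed for well under 1 %
  of draws). Per-gene cleanliness plus guarded spacers implies genome-wide
  exact recovery. The gene's initial Met is exempt from mutation — a
  substituted start codon would make the planted gene undiscoverable and
  the recovery count ill-defined.

Generation is fully reproducible: all randomness derives from the single
config seed, and identical configs produce byte-identical FASTA output.

### What the generator does not emulate

No GC/codon-usage realism, no pseudogenes, no rearrangements or horizontal
transfer, no plasmids, no sequencing or assembly error, and between-family
similarity is uniformly "random protein" — real pan-genomes contain
paralogous families at intermediate distances that make the clustering
threshold genuinely consequential. Passing tests therefore demonstrate the
pipeline's correctness and determinism on separable input, not that the
0.75/0.8 thresholds are optimal for real assemblies.

## Numerical and design choices

* Distances are validated to be symmetric, zero-diagonal and within
  [0, 1] at construction; correlation values clamped to [−1, 1].
* Ties in the screen ordering are broken by cluster id (numeric-suffix
  aware, so Cluster_2 precedes Cluster_10).
* Annotation is a join against a user-supplied `cluster_id → text` table
  with "hypothetical protein" as the default label; keys naming unknown
  clusters are warned about and ignored. No sequence-database search is
  performed or required.
* The pipeline manifest (JSON) records tool version, all parameters, the
  seed, SHA-256 of every input file and per-stage record counts; rerunning
  an identical configuration reproduces result files byte for byte.

## Limitations

Pearson correlation on n = 6 genomes is a screening heuristic: it ignores
phylogenetic non-independence (no tree-aware correction), is sensitive to
single-genome copy-number outliers, and its threshold has no error-rate
interpretation. The clustering is transitive (single-linkage chaining can
merge families through intermediates) and alignment cost grows
quadratically. These are faithful properties of the method the package
implements, stated so users know what they are running.
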