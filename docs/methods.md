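# Methods

This note documents the models, conventions and numerical choices behind
`ctcfevo`, and what the synthetic-data tests do and do not demonstrate about
real data.

## Coordinate and interval semantics

All coordinates are 0-based, half-open (BED convention); narrowPeak summit
offsets are relative to the interval start, and a summit offset of −1 is
replaced by the interval midpoint. The four interval operations fix the
following conventions:

- `intersect` requires a same-chromosome overlap of ≥ `min_overlap` bp
  (default 1); half-open abutment (`end_a == start_b`) is not an overlap.
- `merge` covers exactly the union of its inputs and joins neighbours whose
  gap is ≤ `max_gap` bp, so abutting intervals join at `max_gap = 0`. The
  asymmetry with `intersect` mirrors the interval-arithmetic tools these two
  operations emulate.
- `closest` reports a signed reference-frame distance: the edge gap in bp,
  negative when the neighbour lies at lower coordinates, 0 on overlap.
  Because the distance is a pure edge gap, abutting intervals also report 0
  without overlapping — a measure-zero boundary case the property tests
  exclude. Ties on |distance| break toward the smaller start coordinate;
  strand is ignored. One nearest feature is reported per query.
- `shuffle` re-places each interval uniformly on its own chromosome,
  preserving the (chromosome, length) multiset exactly, rejecting positions
  that touch the exclusion set or an already-placed output, and failing with
  a named-chromosome error after a bounded retry budget. All placements
  derive from a single seeded generator.

## Replicate consensus

Peaks from all replicates are clustered by single-linkage ≥ 1 bp overlap
(the merged union regions define the clusters). A cluster supported by
≥ `min_support` distinct replicates (default 2) yields one consensus
record: its highest-signal member, carrying that member's summit, signal
and −log₁₀ p. Taking every attribute from the single best replicate copy —
rather than averaging across replicates — keeps the record internally
consistent; the support count is appended to the name as `|support=k`.
Under independent per-replicate dropout *q* with 3 replicates and support
2, the expected recovered fraction of true peaks is
3(1−q)²q + (1−q)³ (= 0.896 at q = 0.2), which the consensus stage
reproduces on simulated replicates.

Signal-decile binning sorts by descending signal (ties by chromosome and
start, so the partition is reproducible) and splits into ten near-equal
bins, remainder elements going to the strongest bins first.

## Evolutionary classification

Orthology is consumed as gapless pairwise blocks (7-column TSV), not full
chain/net alignments: each block maps an equal-length interval between the
two genomes, forward or reverse-complemented. A peak maps to the other
genome when ≥ `min_mapped_fraction` (default 0.5, a common
reciprocal-mapping convention) of its length lies inside blocks; the
projection respects block orientation (reverse blocks mirror the
sub-interval within the block). Classification:

- no projection → **subspecies-specific (unaligned)**;
- projection overlapping (≥ 1 bp) a peak of the other subspecies →
  **musculus-common**;
- projection without a partner peak → **aligned-unbound**, kept as a
  distinct third class. Whether such sites belong with the
  subspecies-specific set is a genuine modelling choice; the default
  follows the literal definition (specific = no alignment), and downstream
  class-stratified statistics simply exclude the third class.

Raising `min_mapped_fraction` can only move peaks out of the mapped
classes, never into them (monotonicity, property-tested).

## Repeat content and age

Repeat annotations arrive as an 8-column TSV (one row per RepeatMasker-style
fragment); fragments sharing an element id are merged into one spanning
element whose divergence is the length-weighted mean of the fragments. The
per-peak masked fraction is the union of overlapping repeat bases divided by
peak length; per-superfamily fractions resolve cross-superfamily overlaps by
assigning each base to the lower-divergence (younger) element, a
deterministic rule for a rare ambiguity. Peak "age" is the length-weighted
mean percent divergence of its overlapping elements — a per-peak scalar
suitable for binned summaries. Genome background is the per-superfamily
union coverage divided by total genome length. Enrichment uses an exact
two-sided binomial test of a class's overlap count against a reference
proportion and a chi-square goodness-of-fit across superfamilies, both
Bonferroni-adjusted across classes. Per-signal-bin repeat content reports
the mean of per-peak fractions by default (median available), and empty
bins are reported as missing rather than 0.

## Cross-tissue occupancy and diversity

A liver peak is bound in a tissue when it overlaps (≥ 1 bp) that tissue's
consensus peaks; the cell keeps the −log₁₀ p of the overlapping tissue peak
with the largest overlap (ties → higher significance). The Shannon index is
computed **per site** over tissues: with wᵢ the −log₁₀ p weights of the
bound tissues and pᵢ = wᵢ/Σw, H = −Σ pᵢ ln pᵢ (natural log, the default of
the standard ecology implementation). H = 0 for ≤ 1 bound tissues; an
all-zero weight vector falls back to uniform proportions with a warning.
Conservation per diversity bin uses 10 equal-width bins over the observed H
range (bin construction is not canonical; the count is configurable), with
empty bins missing.

Tissue-sharedness of the focal (subspecies-specific) class: tissues are
ranked by how many focal peaks they share; a peak is **tissue-shared** iff
bound in all `top_k` (default 4) top-ranked tissues *and* the designated
technical-replicate tissue, otherwise **tissue-specific**. The rule is a
strict intersection, so increasing `top_k` never converts specific to
shared.

## Regulatory elements and DE association

Every H3K4me3 consensus peak defines a promoter (with or without
overlapping H3K27ac); every H3K27ac peak not overlapping any H3K4me3 peak
defines an enhancer, so the two kinds partition the histone peaks.
Nearest-TSS distances are signed in gene orientation (negative upstream)
from the peak summit, pooled beyond ±100 kb. Nearest regulatory elements
exclude overlapping elements (overlaps are counted as colocalisation, not
proximity).

A differentially expressed gene (strict FDR < 0.05 on the supplied table)
is associated with CTCF when ≥ 1 classified peak lies within ±50 kb of the
gene **body**. Class assignment is by majority vote with a deliberate
asymmetry: the common class wins only with strictly more common sites than
*either* specific variety; otherwise the gene is associated with a specific
site, shared vs specific decided by the more numerous variety, with the
shared side winning exact ties (the remaining unspecified case). Promoter
assignment at a gene takes at most one promoter overlapping the TSS (larger
overlap, then leftmost); enhancers are counted without positional restraint
in the window. Profiles stratify associated genes into
promoter+enhancer / promoter / enhancer / CTCF-only classes.

## Motif scanning, TAD boundaries and cohesin

PWMs are per-position probability matrices (MEME minimal format) with a
pseudocount and a background (uniform by default). A window scores
Σⱼ log₂(matrix[j][baseⱼ]/background[baseⱼ]) in bits; both strands are
scanned (the reverse-complement motif is scored against the same
background, making the scan exactly strand-symmetric) and windows containing
non-ACGT characters are skipped. The hit threshold defaults to 60 % of the
motif's maximum attainable score — a score-fraction dialect, deliberately
simpler than p-value calibrated thresholds and configurable. Per peak, the
canonical-motif hit closest to the consensus summit wins (ties: higher
score, then leftmost); peaks without any canonical hit are rescanned with
the alternative motifs and the best-scoring alternative hit is used,
flagged non-canonical; peaks with no hit at all are excluded from
orientation statistics.

Each TAD contributes a start and an end boundary (no deduplication across
nested or adjacent TADs). Boundary distance uses the peak summit; a peak is
boundary-associated within ±50 kb. **Favourable** orientation means the
motif points into the TAD interior at its nearest boundary (+ strand at a
start boundary, − strand at an end boundary), consistent with convergent
loop-anchor geometry; the convention is invertible in configuration.

Cohesin regions are maximal segments covered by ≥ 2 of the three subunit
sets (each subunit union-collapsed first), split wherever the set of
covering subunits changes, and annotated with the contributing subunits.
CTCF colocalisation is ≥ 1 bp overlap with any such region; per-class rates
are tested goodness-of-fit against the pooled rate, and co-occupancy is
reported per signal-decile bin per class.

## Statistics

The shared procedures are exact two-sided binomial (tail-probability
summation), chi-square goodness-of-fit (df = categories − 1, expectations
rescalable from proportions), Mann-Whitney U (exact below a combined n of
40 and without ties, tie-corrected normal approximation otherwise — the
standard cutover), Kruskal-Wallis with tie correction, and Bonferroni
adjustment. Degenerate all-equal inputs return p = 1 rather than an error.
Under simulated nulls each test's empirical size at α = 0.05 is calibrated
to 0.05 ± 0.01; for the exact binomial this requires a sample size at which
the discrete attained size approaches the nominal level (n = 250 at
p₀ = 0.5 attains 0.0497), which the calibration test uses.

## Synthetic data: what it emulates

The generator defines the study conditions. Defaults:
three 10 Mb chromosomes; 2000 peak loci per subspecies, 400 bp wide, on a
5 kb minimum-spacing grid; class fractions 0.74 common / 0.20 specific /
0.06 aligned-unbound; 3 replicates with dropout 0.2 and 5 bp coordinate
jitter; B2/B4 SINE insertions under 34 % of specific and 14 % of common
sites with divergence ages N(17, 3) vs N(22, 3) %; background SINE coverage
20 % of the genome (placement count corrected for uniform-overlap
shrinkage, and placements kept clear of peak loci so planted per-class
overlap rates stay controlled); 12 tissues plus a designated replicate
tissue with per-tissue binding probability 0.6 (common) / 0.15 (specific)
and 10 % of specific sites planted bound in all designated tissues; 1 Mb
TADs with 100 kb gaps; favourable-orientation probabilities 0.70 / 0.57 /
0.66 (common / tissue-specific / tissue-shared); cohesin colocalisation
rates 0.80 / 0.50 / 0.78 realised as RAD21+STAG peak pairs (three subunits
with probability 0.3); 1000 genes, 35 % differentially expressed, with
P(down-regulated) = 0.65 for genes whose true association class is
subspecies-specific. Genome sequence is i.i.d. uniform nucleotides except
for near-consensus motif instances planted at peak summits — sufficient for
log-odds scanning, with a per-window chance of a spurious
above-threshold hit of ~2 × 10⁻⁶.

What passing recovery tests shows: the pipeline's operations invert the
generative model they were given, at the planted effect sizes and sample
sizes, with exact interval arithmetic. What it does not show: robustness to
real ChIP-seq artefacts (non-uniform mappability, copy-number bias,
correlated replicate failures), realistic sequence composition, repeat
families whose divergence distributions overlap more strongly, or orthology
maps with gaps and rearrangements. Class fractions reported on jittered,
dropout-affected bundles also shift mechanically: losing a partner peak
from the other subspecies' consensus moves a common peak into the
aligned-unbound class, which is a property of the filtering, not an error
of the classifier.

## Problem sizes and determinism

The test suite and the acceptance script run the recoveries at
2000–6150 peaks per dataset (≥ ~2000 per compared class for rate
recoveries, ≥ 1000 per class for orientation), 10 000 replicates for
test-size calibration, and 200 random instances for interval-oracle
equivalence — sizes at which binomial sampling error sits comfortably
inside the stated tolerances. Every random draw in the package flows from
an explicit seed; generating a bundle twice with the same configuration
yields byte-identical files, and re-running the pipeline yields identical
run-manifest checksums.

## Known limitations

- The motif-scan threshold dialect (score fraction) will not reproduce
  p-value-calibrated hit sets bit-for-bit.
- The orthology importer handles gapless blocks only; chain/net importers
  would be a separate layer.
- Tissue ranking for the sharedness rule is recomputed from the focal class
  itself; with very small focal sets the ranking becomes unstable.
- `closest` reports distance 0 for abutting intervals (see above).
- No FDR procedures beyond Bonferroni are provided; DE tables arrive with
  their FDR precomputed.
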