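# Methods

## Coordinate model and overlap semantics

All intervals are 0-based, half-open (BED convention); any 1-based input
must be converted at the reader boundary. "Overlap" means at least one
shared base everywhere in the package — no minimum overlap fraction is
applied anywhere. Motif-in-peak *containment* is full containment of the
motif interval in the peak interval; a motif ending exactly at a peak end
counts as contained under half-open arithmetic. The five text dialects
(BED6, narrowPeak, BEDPE with ligation count in column 8, UCSC chrom.sizes,
and a blocked-BED ChIA-PET dialect converted to BEDPE on read) are parsed
by line so that malformed input can be reported with its line number, and
writers round-trip every field bit-exactly. narrowPeak strength defaults to
column 7 (signalValue) with a switch to column 5, because labs differ in
which column carries usable strength.

## Anchor and loop scores

An anchor combines a peak and a contained motif as
`anchor_score = peak_score × (motif_score / 10)`. The tenfold weighting of
the peak score reflects that CTCF binding strength varies between cell
types at the same site (DNA-methylation dependent), whereas the motif match
is static; motif scores are treated as caller-supplied and dimension-free,
so hits from any scanner can be used unchanged. When several motifs fall in
one peak, each becomes an anchor — the scan operates on motifs, not peaks.
Loops are scored with the geometric mean of their two anchor scores, which
is less sensitive to a single outlying anchor than the arithmetic mean.

## The directional scan

Within a chromosome, anchors sorted by motif start are processed once:

1. `+` motif, no pending end anchors → append to the start list;
2. `+` motif, pending end anchors → emit every start × end pair as a loop,
   clear *both* lists, seed the start list with the current motif;
3. `−` motif → append to the end list;
4. chromosome end → emit the final start × end block.

Clearing the end list in step 2 is deliberate: the loose reading
("initiate a new list of current start anchors") would retain stale end
anchors and permit loops that end before they start. Unsorted or
multi-chromosome input raises instead of being silently fixed, keeping the
scan auditable. Only the forward scan is run; the reverse scan provably
emits the same pairs.

Nested loops are recovered by repeating the scan at increasing peak-removal
thresholds — by default removing the weakest 0%, 10%, …, 60% of peaks,
counted over the full ChIP-seq peak set (motif-less peaks included) when
that set is supplied. Peaks are ranked by score ascending with ties broken
by (chrom, start) ascending, the lower coordinate removed first, so runs
are reproducible on tied scores. Thresholds are defined on peak
*proportions* by default; a score-quantile mode is provided as an
alternative. The merged prediction set is deduplicated on motif coordinates
and strands (motif positions are stable across datasets, peak intervals are
not), each loop keeping the smallest threshold at which it appeared; anchor
scores never change across thresholds, so loop scores are
threshold-independent.

The stringent subset first gates loops to those shorter than 1 Mb and then
keeps the top 5% by score. Loop length is measured between the inner motif
edges (end-motif start − start-motif end); gate-before-rank is used so a
very strong over-length loop cannot displace in-range loops.

## Validation and the orientation null

A predicted loop is validated when at least one experimental loop is
overlapped at both anchors after extending each anchor motif by 100 bp on
either side. Both anchor pairings (start↔anchor1/end↔anchor2 and the swap)
are tried, since experimental files do not guarantee anchor order.
Experimental ChIA-PET input is first filtered to intra-chromosomal loops
with a ChIP-seq peak at both anchors and at least 3 ligation products; the
stricter count (over the more common 2) trades recall for support quality.
Exact duplicate anchor pairs are deduplicated when replicate files are
concatenated before validation.

The null model permutes the strand labels among the peak-contained motifs —
a permutation, not a resampling, so the counts of + and − motifs and all
positions and scores are conserved — and re-runs the entire prediction
pipeline per permutation. The observed validated fraction is assigned the
upper-tail probability under a normal distribution fitted (mean, sample SD)
to the permuted fractions; a permutation yielding no loops contributes a
fraction of 0, and a zero-variance null degenerates to p ∈ {0, ½, 1} with a
warning. Printed p-values floor at `< 1e-323`, the smallest representable
tail.

## Motif–anchor concordance

For every motif overlapping experimental anchors, each overlapped anchor is
concordant when the motif's 3′ end points into the loop body (+ at the left
anchor, − at the right). Counts and the maximum ligation support per
orientation are accumulated across all loops anchored at the motif. Motifs
hit in both orientations are called discordant only when at least one
discordant loop is supported by more ligation products than every
concordant loop (ties favour concordant). Per-score-bin concordant
fractions use caller-supplied bin edges — no default edges are assumed —
and the overall concordant/discordant split is tested against 50/50 with a
chi-square goodness-of-fit test.

## Binned profiles

Each loop is extended by its own length on both sides and the 3×-length
window is divided into `n_bins` = 30 contiguous bins (10 per flank, 10 for
the body, each 10% of the loop length). Loops whose window crosses a
chromosome end are dropped and counted. Window lengths not divisible by the
bin count use largest-remainder allocation (the first `width mod n_bins`
bins get one extra base), so the grid tiles the window exactly. A feature
counts in every bin it overlaps by ≥ 1 bp; span overlap rather than
midpoint assignment is an assumption, flagged here. Counts are normalised
to FPKM — `count / (bin_kb) / (track_size / 10⁶)` — to cancel bin-size and
track-size differences, then the median across loops is taken per bin.
Because the statistic is a median, a bin is positive only when the feature
occurs there in at least half the loops. Profiles are mean-centred by
default (for cross-mark comparability); variance is never normalised, so
amplitude differences between features are preserved. An uncentered mode
serves absolute-level comparisons.

## Gene classes and expression statistics

Genes overlap loops with their full bodies (the classification concerns
genes, not TSSs). Classes are disjoint and exhaustive: loop (overlaps any
loop body), flank (overlaps an equal-length flanking region and no loop
body — flank membership is revoked in favour of loop), distal (neither).
Flank regions are clipped at chromosome ends rather than discarded, unlike
profiling, where binning forces whole-window rejection; the divergence is
intentional.

Tissue specificity uses `TSI = Σᵢ (1 − Eᵢ/E_max)/(n − 1)` (0 uniform, 1
single-tissue; undefined and reported missing for all-zero vectors) and
variability uses `CV = SD(E)/mean(E)` with the sample (n−1) SD, chosen
because the cell-type panel is a small sample of possible conditions. Class
contrasts report the fold change of medians together with the Wilcoxon
rank-sum test (continuity-corrected) or Welch's t-test; because the
numerator/denominator orientation of a median fold change is ambiguous,
callers choose the order explicitly and the examples print it. Gene-set
enrichment is a generic upper-tail hypergeometric test against any
user-supplied set (e.g. a housekeeping list); no length-bias correction is
applied. Datasets with abnormally low loop-enclosed gene counts are flagged
when they fall more than 2 sample SDs *below* the mean count — high counts
are not treated as suspicious.

## PWM scanner

The built-in scanner is plumbing so the toolkit runs from FASTA plus a
JASPAR-style matrix; it does not reproduce any external caller's exact
p-value machinery. Counts are regularised with a pseudocount (default 0.01)
and scored as log2-odds against a uniform background (both configurable).
A p-value threshold is converted to a score cutoff via the exact
distribution of scores under the background model, computed by
dynamic-programming convolution of per-position score distributions with
configurable rounding granularity (default 1e-3) — equivalent to exhaustive
enumeration but feasible at motif length 19. Minus-strand hits are scored
with the reverse-complemented matrix and reported in forward-strand
coordinates; windows containing N are skipped.

## Synthetic landscapes

The generator defines the conditions under which the package is tested.
Each cluster plants one convergent anchor pair per nesting level (outer
pair flanking inner pairs), + motif left, − motif right, every motif
wrapped in a peak. Outer anchor peaks draw scores from 800–1000, inner from
200–400, and motif-less noise peaks from 450–750 — strictly between the two
anchor classes — so the planted strength ordering (inner < noise < outer)
is unambiguous and nesting is recoverable by proportion thresholding.
Motif scores draw from a narrow 14–16 band so peak strength, not motif
noise, orders the anchors. Defaults: 2 chromosomes of 1 Mb, 5 clusters,
depth 2, 10 noise peaks, 20 noise motifs outside all peaks.

Simulated ChIA-PET files jitter peak-sized anchors by up to 20 bp and draw
ligation counts from a geometric law with mean 4 (a constant law is
available to exercise filter failure); optional decoy loops are placed far
from all true anchors. Feature tracks are Poisson processes with an
elevated within-loop rate. The expression model realises the
housekeeping/inducible dichotomy: housekeeping genes share a log-normal
baseline (median ≈ 50 FPKM) with small cross-cell-type dispersion;
inducible genes are active (log-normal, median ≈ 20 FPKM) in 1–3 of 15
cell types and sit at ≈ 0.05 FPKM elsewhere. All randomness flows through
one seeded NumPy generator; identical config + seed yields byte-identical
files, and the fixture writer emits the same on-disk formats the readers
consume so tests cover the I/O layer.

What the fixtures do *not* emulate: read-level noise, peak-calling
artefacts, motif-score/binding-strength correlation, chromatin-state
heterogeneity, replicate structure, or the long-tailed loop-length
distributions of real ChIA-PET. Passing tests therefore certify the
algorithms' contracts (recovery, monotonicity, determinism, statistical
calibration), not performance on real ENCODE-scale data, where validation
fractions and concordance levels are set by data quality as much as by the
method.

## Problem sizes and numerical choices

The test suite and the acceptance script use landscapes of 5–24 clusters at
depths 1–5 (tens to hundreds of anchors), 200-permutation nulls, 1000
random anchor sets for the scan oracle and a 500-combination grid for the
hypergeometric oracle — sizes chosen so the full stack, including the
byte-determinism double run, completes in seconds while every pathway is
exercised. Degenerate inputs are typed outcomes, not crashes: empty
prediction sets make the validated fraction an error (undefined), empty
score bins report missing rather than 0, all-zero expression vectors give
missing TSI, zero-variance nulls warn. Ties are broken deterministically
everywhere (documented per operation above) so identical inputs give
identical outputs regardless of input ordering.
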