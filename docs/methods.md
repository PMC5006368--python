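# Methods

This note documents the models, conventions and numerical choices behind
`triplesite`, what the synthetic-data generator does and does not emulate,
and the known limitations.

## Coordinates and interval algebra

All coordinates are 0-based, half-open (BED convention); 1-based inputs
must be converted at the boundary. Merging requires a strict overlap of at
least 1 bp: book-ended intervals (`[100,200)`, `[200,300)`) remain
separate regions. This differs from `bedtools merge -d 0`, which joins
abutting intervals; the stricter reading matches the definition of
co-occupied regions as sharing actual bases, and is what the union-find
oracle in the test suite checks. Merged regions carry the label set of
their source intervals, so occupancy classes fall out of the merge
directly.

RPKM is `reads / (kb of region × millions of mapped reads)`. Binned track
comparisons count reads into fixed 10 kb bins and use Spearman rank
correlation over the union of occupied bins (absent bins count 0);
blacklist exclusion is a caller-side pre-filter (`filter_blacklist`).

## Motif model

A motif is a count matrix over A/C/G/T with a pseudocount (default 1)
added to every cell before normalisation. Scan scores are log2 likelihood
ratios against a Markov background of order 0 or 1 estimated from both
strands of the scanned sequences (strand-symmetric by construction, so
scanning a sequence and its reverse complement yields mirror-identical
hits). Windows containing non-ACGT characters are skipped; minus-strand
hits are scored on the reverse complement.

Score p-values are computed under the order-0 marginal of the background
by convolving per-column score distributions. Keys are rounded to 12
decimals (cumulative rounding ≪ 1e-9, the test suite's comparison
tolerance against exhaustive enumeration); above a state cap (2^17) the
lattice is coarsened to 1e-4 bits, trading exactness for memory. Scores
obtained under an order-1 background are looked up in this order-0 null —
a deliberate approximation, because the exact order-1 null depends on
window context; p-values under order-1 scanning are therefore
approximate, and thresholding remains monotone in score.

Conventions: the motif "center" is the base immediately 3′ of the
midpoint in motif orientation for even widths (mirror-symmetric between
strands), the middle base for odd widths. The best hit per region is the
maximum score with ties broken to the leftmost start, then + before −.
Control matrices are produced by column-order permutation, which
preserves per-column composition and total information content.

## Occupancy classes and category comparisons

`classify_occupancy` merges the pooled peaks of ≥2 factors and labels
each merged region with the set of factors contributing ≥1 overlapping
peak; the category table counts merged regions per class (the per-factor
peak RPKM table counts original peaks — both views are reported where
relevant). Class signal comparisons use one-sided Wilcoxon rank-sum tests
in the direction of the larger median, BH-adjusted within each factor's
family; groups under 2 observations are flagged and skipped. Rank tests
use scipy's Mann–Whitney implementation, exact for small tie-free
samples and asymptotic with tie correction otherwise.

`overlap_enrichment_test` re-places query intervals (lengths preserved)
uniformly within a user-supplied workspace and reports the empirical
p-value `(1 + #{null ≥ observed}) / (n_sim + 1)`. No mappability or
isochore stratification is attempted; the null is plain uniform
placement. With few query regions the observed fraction is coarsely
discrete, ties with the null inflate the p-value, and the p-value is
therefore valid (super-uniform) rather than exactly uniform — the
calibration test asserts exactly that property.

Cross-tissue sharing counts tissues overlapping a peak by ≥1 bp;
"constitutive" means strictly more than the threshold (default 7; exactly
7 does not qualify). Cross-species categories: "Beyond rodents" if shared
with any non-rodent (human or dog), else "Rodents only" if shared with
rat, else "Mouse only"; orthology flags are inputs, not computed.

## Oriented offsets and ordering

For a motif at center *c* with G-rich orientation *s*, the oriented
offset of a summit *x* is `x − c` when *s* = + and `c − x` when *s* = −;
negative offsets are 5′ of the motif in its reading direction.
"Un-oriented" offsets are `x − c` regardless of strand. Sites enter the
ordering analysis only if every factor's summit lies within ±100 bp of
the motif center; excluded sites are counted. The ordering label sorts
factors by ascending oriented offset (CTCF is represented by its own peak
summit, not by the motif center; exact ties break alphabetically and are
flagged). Orientation enrichment is a Fisher exact test on canonical vs
non-canonical counts, before vs after orientation.

Relative domain position is `(anchor − start) / size` for the domain
containing the anchor (motif center when available, else summit): 0 at
the 5′ border, 1 at the 3′ border; translation-invariant by
construction. Border enrichment compares per-unit densities in the outer
10% of either end against a 10%-wide window around the center.

## ChIP-exo profiling

The 5′ end of a read is its start on + and `end − 1` on −. Profiles
count 5′ ends at each offset in ±50 bp of oriented motif centers,
separately per strand, and divide total counts by the number of retained
regions. Regions with fewer than `min_reads` (default 10) 5′ ends inside
the window — not merely overlapping reads — are discarded. For
minus-oriented motifs, offsets are mirrored **and** strand labels
swapped, so "forward" always means the top strand in the motif's own
reading direction and a statement like "reverse-strand protection at
−27..−13" is independent of the genomic strand of the motif.

The background envelope re-scans the peak regions with column-permuted
matrices, re-orients on the best permuted hit per region, re-profiles the
same reads and summarises per-offset mean/sd/min/max over permutations.
Because column permutation preserves letter composition, a consensus with
repeated letters can be re-found at a small shift, which would re-center
background windows on the true footprint and contaminate the envelope
with shifted signal; permuted hits overlapping the region's best original
motif hit are therefore excluded by default (`exclude_original_overlap`),
restoring the envelope's role as a composition control. Footprints are
maximal runs of ≥3 consecutive offsets where the observed profile exceeds
background mean + k·sd (default k = 3); a single-offset spike is never a
footprint. Both the run length and k are package choices — the underlying
experiments are usually summarised as profile plots.

## Allele-specific binding

Allele frequency is `ref / (ref + alt)` (reference = C57BL/6J in the
F1-cross setting). Bias classification is an exact two-sided binomial
test against 0.5 using the minimum-likelihood convention (sum of both
tails at least as extreme); at coverage 20 and α = 0.05 the discreteness
makes the realised type-I rate ≈ 0.041, which the calibration test brackets
in [0.02, 0.07] rather than asserting 0.05. Sites below a configurable
minimum coverage (default 5 informative reads) are excluded. Co-binding
is the Pearson correlation (Spearman optional) of two factors' allele
frequencies at shared sites; the group-shift test compares the target
factor's frequencies in the anchor's biased classes against its unbiased
class, greater-sided for reference-preferring anchors and less-sided for
alternate-preferring ones.

## Profiles and supercoiling

Summit-centered profiles average point-feature counts per bp in ±1.5 kb
windows, split into TSS-proximal (<1 kb to the nearest TSS) and distal
classes; proximal windows are flipped when the nearest TSS is on the
minus strand so transcription always points right. Expression grouping is
mean ± sample SD (strict inequalities; boundary values are "medium";
optionally on log2(x+1)). Subtracted coverage extends each read to 150 bp
from its 5′ end in read orientation, scales both tracks to reads per
million, and subtracts input from ChIP per bp. Per-bp score-track
profiles (e.g. conservation scores) average track values at oriented
offsets in ±150 bp, excluding missing positions per offset.

bTMP normalisation is `log2(cell/input) − log2(genomic/input)` — the
genomic-DNA channel corrects probe affinity and the value is invariant
under common rescaling. A `literal_minus` variant computing
`log2(cell/input) − log2(genomic − input)` is provided for comparison;
the default is the dimensionally consistent ratio form, and neither is
asserted as uniquely correct.

The supercoiling profile assigns each probe (midpoint) to its nearest
oriented feature (ties to the 5′ feature; probes beyond 50 kb excluded),
bins signed oriented distances by 100 bp, takes per-bin medians (empty
bins stay undefined; no interpolation) and smooths with a rolling mean of
10 bins advancing 2 (output length `floor((n − window)/step) + 1`). The
control repeats the pipeline on 10 uniformly re-drawn feature sets of
equal size and averages their smoothed profiles.

The observed/control comparison is a two-sample Kolmogorov–Smirnov test,
applied to **unsmoothed** bin medians computed from `n_random + 1`
disjoint random subsets of the probes (one subset for the observed
sample, one per control replicate, pooled). Three dependencies would
otherwise break the KS null and were each confirmed empirically to skew
the null p distribution: adjacent smoothed values share most of their
window; observed and control medians computed from the same probes are
coupled; and control replicates re-binning the same probes are coupled
with each other. With disjoint subsets the null p-value is uniform, while
the reported profile and plotted background still use every probe.

## The synthetic-data generator

Every generator is a pure function of a `SimulationConfig`; distinct seed
streams per generator make outputs independent of call order, and a fixed
seed gives byte-identical files (`write_dataset`). Defaults encode the
spatial statistics the analyses are designed to detect, so a default run
produces data that "look like" the biology the package targets:

- **Sites and genome.** Motif centers evenly spaced (≥1.5 kb, jittered)
  with strands alternating +/−, embedded in i.i.d. uniform background
  sequence as column-wise samples from the motif matrix. The default
  matrix is a 14-column G-rich CTCF-like consensus at ~22 bits, sharp
  enough that a p ≤ 1e-4 scan recovers ≥95% of planted instances.
  Consecutive +/− site pairs share their drawn occupancy class and
  oriented offsets, making the planted un-oriented offset distribution
  exactly mirror-symmetric — its median is zero by construction, part of
  the planted truth rather than a sampling outcome.
- **Peaks.** Occupancy classes drawn per pair from the configured split
  (default 50% triple / 49% CTCF+RAD21 / 1% CTCF+TOP2B); member summits
  at orientation-corrected Normal offsets (defaults TOP2B −15 ± 5 bp,
  CTCF 0 ± 5, RAD21 +12 ± 5), widths Uniform(200, 400), lognormal signal
  boosted ~2× at triple sites. Reads are fixed at 36 bp.
- **Exo reads.** Per site, each read is noise with probability 0.2 (5′
  end uniform in ±50 bp, either strand) or signal (5′ end uniform over
  the planted footprint: forward +13..+26, reverse −27..−13), mapped back
  through the site orientation.
- **Allelic counts.** A per-site bivariate-normal logit bias (total SD
  1.2) squashed through the logistic and sampled binomially at coverage
  20. The latent correlation is solved analytically (two-dimensional
  Gauss–Hermite quadrature plus root-finding) so the induced Pearson
  correlation of allele frequencies matches the configured target
  (default 0.4) after logistic squashing and binomial sampling noise — a
  calibration by construction, not by simulation.
- **Probes and domains.** Probes on a jittered 200 bp grid; values are
  Gaussian noise (SD 0.25) plus a planted dip (depth −0.5, σ = 300 bp)
  around the nearest site. For supercoiling studies features are planted
  uniformly i.i.d. (`plant_uniform_features`) so the observed and
  random-control distance distributions match — real regulatory features
  are irregularly spaced, which uniform placement emulates better than
  the even spacing used for peak simulation. Domains tile each chromosome
  at sorted uniform cuts; half of the sites (configurable) are re-placed
  within the outer 10% of a random domain.

What the generator does **not** emulate: fragment-length and PCR
artefacts, mappability structure, chromatin-state-dependent backgrounds,
SNP-level allelic read assignment, copy-number or GC biases, and
correlated peak widths/signals along the genome. Recovery tests therefore
demonstrate the correctness of the statistical machinery on data
satisfying the model's assumptions, not robustness to every artefact of
real sequencing data.

## Problem sizes

The validation suite runs at sizes chosen to keep each stage's planted
effect comfortably detectable: 10,000 sites for occupancy proportions,
2,000 for directionality and domain positions, 500 sites × 50 reads for
footprinting, 5,000 sites at coverage 20 for allelic statistics (500
replicates of 300 sites for null calibration), and 200-replicate nulls of
~2,000 probes for supercoiling calibration. The acceptance script uses
the same sizes.

## Known limitations

- Order-1 backgrounds get order-0 p-values (documented approximation).
- The GAT-style randomisation ignores mappability/isochore structure.
- The supercoiling KS test sacrifices a little power (split samples) for
  calibration; with strong dips this is immaterial.
- Exact Wilcoxon enumeration is unavailable under ties; large-sample
  tie-corrected p-values are used instead.
- The 5′/3′ tie-break for equidistant probe-to-feature assignment and
  the probe-midpoint convention are fixed choices; alternatives would
  shift profiles by at most one bin.
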