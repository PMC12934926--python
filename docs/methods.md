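# Methods

## Overview

`ddpheno` turns base-level RNA-seq coverage into per-gene latent
phenotypes suitable for cis-QTL mapping and TWAS. The procedure has
four stages:

1. **Regions.** Each protein-coding or lncRNA gene is phenotyped over
   its annotated span plus a 1 kb flank on each side (`flank_bp`,
   default 1000). All internal coordinates are 0-based half-open; GTF
   input is converted on parse. Strand does not alter region
   construction or bin ordering; it is recorded and used only for TSS
   reporting in the BED export.
2. **Bins.** The region is segmented into bins adapted to coverage
   variation (below), oversized bins are subdivided to at most
   `max_bin_size` = 1024 bases, and any bin overlapping an exon of a
   *different* gene — any gene in the annotation, regardless of
   biotype — is removed to limit cross-gene read contamination.
3. **Normalization.** Per-bin mean coverage per sample is divided by a
   per-sample depth factor (the sample's total binned coverage over all
   genes' kept bins, relative to the cohort median total), then
   log2-transformed after adding a pseudocount (default 8).
4. **Phenotypes.** Each gene's normalized bin matrix is standardized
   per bin and decomposed with PCA. Sample projections onto the
   retained components are the data-driven phenotypes (DDPs). With a
   table of knowledge-driven phenotypes (KDPs), each bin is first
   residualized against the gene's KDPs, and the same PCA machinery
   yields residual DDPs (rDDPs).

## Variance-adaptive segmentation

The segmentation statistic for a gene is the per-base *variance
profile*: for each pair of consecutive bases, the per-sample first
difference of log2(coverage + pseudocount) is computed, and its
variance across samples (ddof = 1; the unbiased estimator — a choice
this package makes explicitly) is recorded. The profile has length
(region span − 1).

Scanning left to right, profile entries accumulate until the running
sum reaches a global threshold; the bin then closes *after* the base
whose entry triggered the threshold, and the accumulator resets to
exactly zero (no carry-over of the excess). The final partial bin is
kept. Regions with more coverage variation therefore receive more,
smaller bins. The scan is implemented with `searchsorted` on the
profile cumulative sum, which reproduces the naive accumulator scan
exactly (tested against a python-loop oracle).

The threshold is shared by all genes. It is calibrated on a seeded
random sample of up to 128 genes and 256 samples by bisection on
log-threshold, targeting a mean of 256 bins per gene within 2% (at
most 40 iterations). Mean bin count is a monotone non-increasing step
function of the threshold, so bisection converges onto the plateau
containing the target. Calibration counts bins **before** subdivision
and exon exclusion: those two steps depend on `max_bin_size` and on
the local annotation rather than on coverage variation, so counting
before them keeps the calibrated quantity a pure function of the
segmentation statistic. One seed controls both the gene and sample
draws and is recorded in scheme provenance.

Bins wider than 1024 bases are split into ceil(w/1024) contiguous
pieces whose widths differ by at most one base, longer pieces first.
A fixed-width uniform binning (`uniform_bins`) is provided as a
benchmarking alternative and shares the exon-exclusion code path.

## Normalization details

The depth factor for sample *s* is T_s / median(T), where T_s sums the
sample's raw per-bin mean coverage over every phenotyped gene's kept
bins. "Cumulative coverage" is thus defined over pipeline state rather
than genome-wide coverage, which keeps model application self-contained:
factors are recomputed per dataset being quantified, training or
otherwise. The order of operations is fixed: scale, add pseudocount,
log2.

## Per-gene PCA

Genes are modeled only if they have nonzero total binned coverage in
at least 50% of samples (inclusive boundary); the same filter is
re-applied, on the target dataset's samples, before model application.

Standardization subtracts the per-bin training mean and divides by the
per-bin training SD (population SD, ddof = 0, matching the common
scaler convention); zero-variance bins get SD 1 so they contribute a
constant zero. Components are retained up to the smallest k whose
cumulative explained-variance ratio reaches 0.80, capped at 16 and at
the rank bound min(#bins, #samples − 1) — the −1 because mean-centering
consumes one degree of freedom. A gene whose standardized matrix has
zero total variance yields a model with zero components rather than an
error, since such genes can slip past the coverage filter (constant
nonzero coverage).

PCA sign is arbitrary, so a deterministic convention is applied: each
component is flipped, if needed, so that its largest-|loading| bin
(ties broken toward the lowest bin index) has a positive loading.

At application, new data is standardized with the **training** means
and SDs stored in the model, so phenotype dimensions correspond across
datasets; bin IDs must match the stored scheme exactly, and mismatches
are an error instructing re-binning. Fitting is per gene and
streaming; results are independent of batching by construction.

## Residualization (rDDPs)

For each bin of a gene, a two-pass screen removes KDP signal:

1. OLS of the bin's normalized values on an intercept plus *all* of the
   gene's KDPs jointly; each KDP gets a two-sided t-test p-value with
   df = n − rank(design).
2. KDPs with p < 0.01 are retained; a second OLS on the retained set
   alone produces the predictions that are subtracted. If nothing is
   retained, the residual is the mean-centered response.

Joint (not marginal) first-pass regression is the default reading of
"all KDPs as features". The solver uses the pseudoinverse, so collinear
KDP sets degrade gracefully; a coefficient in the design's null space
(e.g. an all-zero KDP) gets p = 1 and is never retained. The null-space
test depends only on the design geometry, so an exact fit (zero
residual variance) still assigns p ≈ 0 to its true predictors.
Residuals are exactly orthogonal to the intercept and every retained
KDP, and residual variance never exceeds the original per-bin variance.

Samples with missing KDP values are excluded from the fits; predictions
for them use mean-imputed KDPs; more than 20% missing samples is
refused. Genes absent from the KDP table are fitted as plain DDP models
with a warning by default (configurable to drop).

## Synthetic data

The simulator generates what the pipeline consumes — GTF, per-sample
bigWig (or lazy in-memory coverage), and matched KDPs — with known
latent structure. Each gene is a mixture of isoforms (exon subsets of
a shared layout; the second isoform skips an internal exon). Per gene
*g* and sample *s*, an expression factor e ~ N(0, σ_e²) and a usage
factor u ~ N(0, σ_u²) drive expected coverage

    d_s · 2^e · Σ_i w_i(u) · baseline · 1[base ∈ exons of isoform i],

with softmax isoform weights w(u), a log-normal per-sample depth
multiplier d_s ~ LogNormal(0, σ_d²), and Poisson noise per base
(negative binomial is not implemented; Poisson keeps the mean–variance
link simple and sufficient for the recovery properties tested).
Expression factors are drawn per gene rather than per sample: a
sample-wide expression shift is mathematically indistinguishable from
sequencing depth and would be removed by depth scaling.

Defaults (10 genes of 5–50 kb, 100 samples, σ_e = σ_u = 0.5,
σ_d = 0.2, ~20× exonic coverage) describe a small cohort with moderate
biological variation. Coverage noise is keyed per (gene, sample) so any
subset of samples or regions reproduces identical values and population
genomes never need to be held in memory at once; the bigWig writer and
the in-memory source produce identical values by construction.

What the simulator does *not* emulate: read-level artifacts (splice
junction softclips, positional bias, mappability), fragment-length
effects, correlated noise across samples, and annotation errors.
Passing recovery tests therefore demonstrate correctness of the
pipeline's statistical machinery under its own generative assumptions,
not performance on real tissue data.

Simulated KDPs are the quantities an annotation-based quantifier would
ideally produce: log2 expected total gene output (depth excluded) for
expression, and the first isoform's usage weight for isoform ratio,
with optional Gaussian noise.

## Problem sizes used in the shipped analyses

The packaged checks run at desk scale: unit and property tests use
toy matrices and a 6-gene/60-sample simulated population; the latent
recovery suite uses 5 genes × 500 samples; the reproduction script's
calibration analysis uses a 150-gene genome with 256 samples, chosen
to exercise the full 128-gene calibration draw.

## Numerical choices and edge cases

- Accumulator segmentation uses cumulative sums; ties at the threshold
  close the bin (>= comparison).
- Bisection bracket for calibration: [1e-8, max per-gene profile mass],
  geometric midpoint.
- All-zero variance profiles produce a single bin; calibration errors
  out only if *every* calibration gene is flat.
- A 1-base overlap with a foreign exon removes a bin; touching
  intervals ([a,b) vs [b,c)) do not overlap.
- Matrix TSVs serialize floats at 17 significant digits, so round-trips
  are exact to well below 1e-9.
- Model archives embed a format-version string and refuse to load
  other versions; writes are atomic (temp file + rename).

## Known limitations

- Foreign-exon exclusion is binary; a probabilistic assignment of
  shared coverage is out of scope.
- No GC/mappability correction or quantile normalization; downstream
  QTL tooling is expected to apply its own inverse-normal transform.
- The uniform binning alternative uses a fixed width over the whole
  region, without coding/noncoding awareness.
- Chromosome-name aliasing handles only the "chr" prefix.
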