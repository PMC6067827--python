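# Methods

`normsig` studies a deceptively simple question: given a two-class bulk
expression cohort with pervasive sample heterogeneity, how much does the
choice of normalization change what you find — which genes look
differential, how accurate a classifier seems, and whether a selected gene
signature is demonstrably better than a random one?  The package implements
the complete comparison for four regimes and a synthetic cohort generator
with known ground truth.

## Preprocessing

Raw intensities are natural-log transformed (non-positive entries are an
error unless an explicit offset is configured — nothing is silently
shifted) and median-centered **within each sample**.  Per-sample centering
is deliberate: any statistic computed across samples (a cohort mean, a
pooled quantile) makes one sample's processed values depend on which other
samples happen to be in the batch, which is exactly the irreproducibility
the pipeline is designed to expose.  A detection filter can drop genes
whose detection p-values are unfavourable in too many samples; the standard
bead-array convention (detection p > α means undetected, default α = 0.05,
`discard_above`) is the default, with the inverted reading selectable
because published descriptions of this step are sometimes ambiguous.

## The four normalization regimes

**Log-only ("none")** is the negative control: no cross-sample adjustment
at all.

**Quantile** forces every sample's value distribution onto a common
reference, the rank-wise mean of the sorted training columns.  Tied values
receive the mean of the tied reference positions.  The reference is fitted
on training samples only and applied frozen to held-out samples, so the
transform is rank-invariant per sample and free of test-set bias.

**Gene fuzzy scoring (GFS)** is an unsupervised per-sample rank transform
with two thresholds θ1 < θ2 (defaults 0.05 and 0.15; the useful ranges are
roughly θ1 ∈ [0.05, 0.10], θ2 ∈ [0.15, 0.20]).  With descending rank r
(rank 1 = highest expression, ties averaged) and rank cutoffs q1 = θ1·n,
q2 = θ2·n:

    s = 1                      if r ≤ q1
    s = (r − q2)/(q1 − q2)     if q1 < r < q2
    s = 0                      if r ≥ q2

GFS is exactly invariant to any strictly increasing per-sample transform
and bounds every gene's influence to [0, 1] — a soft top-coding that
suppresses heavy-tailed artifacts and diffuse correlated variation at the
cost of discarding everything below the top ~θ2 of each profile.  A
consequence worth knowing: GFS can only see class signal in genes whose
expression crosses the top-rank band between the classes.

**SVA-lite** is a simplified two-step surrogate-variable correction: fit
per-gene class means, take the SVD of the residual matrix, keep k
right-singular vectors, and regress each gene on class + surrogates,
storing the surrogate coefficients; correction subtracts the surrogate
contribution, with the class term protecting class-attributable variation.
This is the residual-SVD outline of surrogate-variable analysis, not the
full iteratively reweighted algorithm — the package is self-contained by
design.

Two numerical choices deserve explanation:

* **k selection** uses permutation parallel analysis: each gene's residuals
  are permuted independently across samples (B = 20 permutations), and k is
  the leading run of observed singular values exceeding the null's 95th
  percentile *by at least 2%*.  The margin matters: under pure noise the
  observed and permuted spectra are exchangeable and agree to well under
  1%, so without it k = 1 would fire at roughly the 5% rate on structureless
  data, while a genuine planted factor of ≥ 1 sd exceeds the threshold
  severalfold.
* **Every sample is corrected by projection** — its residual from the
  stored training gene means is projected onto the frozen gene-space
  directions (uᵢ·resid/sᵢ) and the fitted per-gene surrogate contribution
  is subtracted.  An earlier variant corrected training samples with their
  exact stored scores and only new samples by projection; that treats the
  two populations systematically differently (the exact scores are
  orthogonalized against class, projections are not), and in cross-
  validation it manufactured shrunken-centroid features that looked clean
  on the training half and noisy on the validation half, collapsing SVA's
  held-out accuracy to chance.  Uniform projection restores
  exchangeability; k = 0 models are the identity.

## Diagnostics and selection

PCA treats samples as observations, centers genes, does not scale (unit
scaling would distort GFS's [0, 1] structure), and fixes signs by making
the largest-magnitude loading entry positive.  Each of the top 10 PCs is
tested against every categorical factor with the tie-corrected
Kruskal–Wallis test; the grid of raw p-values (no correction across the 30
cells — a caveat, not an oversight: the table mimics the raw-threshold
convention of exploratory use) summarizes which factors dominate which
components, and the first class-significant PC is a compact per-regime
diagnostic.

Differential expression is the one-way ANOVA F per gene with
(K−1, N−K) degrees of freedom, with explicit degenerate conventions
(zero within-group variance with non-zero between → F = ∞, p = 0; fully
constant → F = 0, p = 1), followed by Benjamini–Hochberg step-up
adjustment.  A signature is the genes at adjusted p ≤ 0.01 (strict) or
0.05 (relaxed), ordered by raw p with lexicographic tie-break.

## Cross-validation and the random-signature null

Both experiments repeat stratified 50/50 splits (28 + 14 of 56 + 28 per
half — stratification is a deliberate reading of "evenly split", since
unstratified halves can lose a class entirely).  Quantile and SVA are
refitted inside each split on the training half only.  The classifier is
the nearest shrunken centroid: standardized centroid deviations
dᵢₖ = (x̄ᵢₖ − x̄ᵢ)/(mₖ(sᵢ + s0)) with mₖ = √(1/nₖ − 1/N) and s0 the median
pooled sd (falling back to the mean positive sd when more than half the
genes are within-class constant, which happens after heavy top-coding),
soft-thresholded by Δ; prediction minimizes the standardized distance to
the shrunken centroid minus 2·log prior, ties toward the first declared
class.  Δ is chosen by stratified inner 5-fold CV over a 30-point grid from
0 to max|d|, preferring the largest Δ among accuracy ties.

The with-selection experiment selects a signature on the training half at
adjusted p ≤ 0.01, evaluates it on the validation half, and in the same
split draws a uniformly random gene set of the same size from the full gene
universe (independent random stream) and evaluates it identically.  The
empirical p is the fraction of splits in which the random signature is
*strictly* better; ties favour the observed arm.  Splits with an empty
signature are excluded from medians and counted; if every split is empty
the empirical p is reported as 1.0 — there is then no evidence whatsoever
that selection beats chance, and reporting NaN would make the regime
comparison undefined.  Selection stability is summarized by per-gene
selection frequency and the mean pairwise Jaccard similarity of split
signatures (our definition; 1 = identical every split, 0 = pairwise
disjoint).

## The synthetic cohort

No public data accompany the design this package targets, so the generator
is a first-class, tested component.  It plants, on the natural-log scale:
a per-gene baseline ~ Normal(7, 1.5) (a plausible bead-array dynamic
range); 20 signal genes shifted by 1.0 in the 56 cases; gender and
ethnicity covariates (75/25 within each class, 30 genes each, 0.8 shift);
heterogeneity; and i.i.d. Normal(0, 0.5) noise, exponentiated to raw
intensity space.

Signal-gene baselines are drawn near the 0.93 quantile of the baseline
distribution (jitter sd 0.25).  This is a modelling statement, not a
convenience: on arrays, differential signal is detectable only in genes
that are well expressed, and a rank-based transform can only register a
shift that moves genes through the top of the profile.  Placing the signal
mid-distribution would declare by fiat that rank methods cannot work.

Heterogeneity has three layers, chosen to emulate what array cohorts
actually contain rather than what any one correction method is best at:

* a leading latent factor (strength 1.2) on 40% of genes with per-gene
  Normal(0,1) loadings, whose per-sample score has correlation ρ = 0.3 with
  the class indicator — the "heterogeneity partially aligned with class"
  regime in which random signatures also predict;
* 8 minor factors (strength 0.5 each) on the same genes — diffuse
  correlated variation that a low-rank correction estimated from 42
  training samples recovers only partially;
* sample-specific artifacts: 3% of entries spiked by Normal(0, 3), and a
  per-sample log-normal (sd 0.6) scale factor applied around each sample's
  median — neither is low-rank, the scale factor is invisible to rank
  methods and removable by quantile normalization, and the spikes are
  bounded in influence only under GFS.

Under these conditions the four regimes genuinely differ, and in the
direction the comparison is designed to probe: log-only data are crushed by
all three layers; quantile fixes the distribution-shape layer only; SVA
removes the leading factor(s) but pays for the diffuse floor and the
artifacts; GFS bounds everything while the top-placed signal survives.
Zeroing the class effect and all heterogeneity yields a calibrated null
(uniform F-test p-values, ~5% type-I error, chance-level CV at the 2/3
majority rate).

What the generator does **not** emulate: probe-level effects, intensity-
dependent variance, count noise, correlated gene modules unrelated to the
latent factors, label noise, or batch structure aligned with processing
date.  Passing tests on this generator show the pipeline's internal logic
and the relative behaviour of the regimes under the stated model — they do
not certify performance on any particular real cohort.

One asymmetry with published experience is worth flagging: on real
bead-array cohorts log-only data typically produce *thousands* of BH hits
(heterogeneity masquerading as signal), whereas under this generator the
heteroscedastic scale layer inflates within-group variance and makes
log-only selection conservative instead.  The downstream conclusion — that
log-only signatures are no better than random — is the same, but the
mechanism differs.

## Reproducibility and problem sizes

All randomness descends from master seeds through named
`numpy.random.SeedSequence` substreams (splits, random signatures,
permutations, simulation), so every experiment is bit-reproducible and the
pipeline summary is byte-identical across reruns with the same seed.  The
default synthetic cohort uses 2,000 genes (a scaled stand-in for an ~18k
probe panel — every statistic involved scales per-gene, so the comparison
is unchanged while experiments stay interactive); the bundled experiments
use 100–200 splits per regime and 3–5 seeds, sizes at which the regime
ordering and the empirical-p contrast are stable.

## Known limitations

* SVA-lite is not the full iteratively reweighted algorithm; with
  heterogeneity strongly aligned with class (|ρ| near 1) the protection of
  class-attributable variation becomes ill-posed for any method of this
  family.
* The empirical p resolution is 1/n_splits; at 200 splits values below
  0.005 are reported as 0.
* The Δ grid is linear with 30 points; pathological deviation spectra could
  warrant a finer or log-spaced grid.
* Hierarchical clustering supports Ward and average linkage (both appear in
  published descriptions of this analysis); the default is Ward, and the
  2-cluster cut accuracy uses the better of the two label matchings.
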