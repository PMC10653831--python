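# Methods

This note documents the statistical model, the numerical choices, and
the design decisions behind `damdiff`, and states what the simulation-
based tests do and do not establish about real data.

## Coordinates and the unit of analysis

All internal coordinates are 0-based, half-open (BED-native; VCF input is
converted on read; human-facing reports print 1-based positions).  A GATC
palindrome with its G at forward-strand position *s* has methylatable
adenines at *s*+1 (forward strand) and *s*+2 (the adenine of the
reverse-complement reading).  Chromosomes are circular by default —
origin-spanning motifs are found by scanning the doubled sequence and
de-duplicating starts modulo the length — with a flag for linear contigs.
The unit of testing is the strand-specific adenine, not the pooled
palindrome: strand-level effects (hemimethylation) are real biology and
pooling is lossy; pair-level summaries are derived afterwards.  A pair is
*methylated* when both strand β values are ≥ 0.60, *hemimethylated* when
exactly one is below, *hypomethylated* when both are; the 0.60 threshold
is a config value and the comparison is strict (<).

## Filtering and count normalization

A site enters an analysis only if **every** sample in the comparison
covers it with ≥ 10 reads (the per-sample-all reading; a per-comparison
mean would let one shallow sample dilute a site's counts unnoticed).
Missing cells exclude a site from any computation involving that sample;
nothing is imputed.

"Median coverage normalization" is implemented as: for sample *i* with
per-sample median coverage *m.i*, target *m\** = median over samples of
*m.i*, factor *f.i* = *m\**/*m.i*; coverage and methylated counts are
both multiplied by *f.i* and rounded to the nearest integer
(ties-to-even), methylated clipped into [0, coverage].  This choice is
symmetric across samples and idempotent on homogeneous data, keeps counts
valid binomial data for the logistic model, and perturbs each cell's β by
at most 1/coverage (a tested invariant).  The factors are recorded on the
returned table for output metadata.

## The differential test

Per site, per-sample methylated/unmethylated read counts are modelled as
binomial with a logit-linear predictor containing only the group factor.
Significance is the likelihood-ratio χ² (df = levels − 1) of the group
model against the intercept-only model.  Because the only covariate is
categorical, the MLE fits each group at its pooled proportion and the
binomial log-likelihood depends on the per-sample counts only through the
group totals, so the LRT is computed in closed form, vectorized across
sites; the test suite verifies identity with an IRLS-fitted GLM.  Under
complete separation (a group at β = 0 or 1) the deviance is evaluated
with the 0·log 0 = 0 convention and remains finite; the p-value is
extreme but well-defined, which is the correct behaviour for a
boundary MLE.  The effect size reported is the pooled percent-methylation
difference (treatment − reference), used only for the call rule, never
for the test statistic.

A site is *called* when q < 0.05 and |difference| > 10 percentage points,
both strict.  Reported q-values come from Benjamini–Hochberg or from a
SLIM-style procedure: the empirical CDF of the p-values is evaluated on a
λ grid, an OLS line is fitted within a sliding window, and π₀ is the
slope of the best-fitting window in the flat upper region of the grid
(bounded into (0, 1]); q = monotonized π₀ · m · p / rank.  Because the π₀
fit is unstable on short vectors, fewer than 100 p-values fall back to
BH; the method used is recorded in the output.  No overdispersion
correction is applied — the binomial logistic model is the method being
provided — but the calibration consequences are documented below.

Calibration caveats, measured by the test suite: the LRT χ² approximation
is accurate at moderate β (≈0.9) under realistic variable coverage, and
anticonservative very close to saturation (β ≳ 0.97, where expected
unmethylated counts per group are ~5); and any extra-binomial replicate
variability (drift) inflates the null beyond nominal.  The >10-point
difference filter is what keeps practical false calls near zero in both
regimes — the tested property is that the *call* rule, not the raw
p-value, controls errors.

## Feature statistics

M-values are M = log₂(β / (1 − β + 0.001)).  The 0.001 offset keeps β = 1
finite (M ≈ 9.97); β = 0 maps to −∞, which the rank-based tests downstream
treat as the most extreme observation.  The transform is strictly
increasing on (0, 1], so rank tests are unaffected by the offset's exact
placement.  Feature classes are compared to the genome-wide median M by a
one-sample Wilcoxon signed-rank test (exact null for n ≤ 25, normal
approximation with continuity correction above; zero differences dropped;
all-at-median is degenerate with p = 1), BH-corrected across features;
classes are compared to each other by tie-corrected Kruskal–Wallis (an
all-tied input returns H = 0, p = 1 rather than an error).

Promoter profiles align sites by strand-aware signed TSS offset (negative
= upstream in the direction of transcription), take the per-offset median
β within ±300 bp, and smooth by a running median over a ±25 bp
half-window of occupied offsets.  The running median replaces
quantile-regression spline smoothing; it affects visualization only and
its bandwidth is configurable.

Enrichment of differential sites in a feature class uses the one-tailed
(enrichment) Fisher exact test — the hypergeometric upper tail of the
2×2 partition of the universe — BH-corrected within a direction.  The
default conditioning universe is the post-filter tested site set (the
sites that *could* have been called), with the option to condition on the
full ancestral census instead.  Sites outside genes are attributed to the
gene with the nearest boundary on the circular chromosome, ties broken
toward the downstream gene on the + strand.  Term over-representation is
a plain hypergeometric test over a user-supplied gene→term map with
BH-filtering at q < 0.05 and exact-membership de-duplication of redundant
terms; no live annotation database is consulted.

## Ordination

β-values depend on coverage, so before computing between-sample distances
the coverage matrix is quantile-normalized (rank → across-sample mean of
order statistics; tie groups receive the mean of the order-statistic
means they span), an OLS scaling line of normalized on raw coverage is
fitted per sample, and that affine map is applied to both the coverage
and the methylated counts — the literal reading of applying the sample's
"scaling equation" to both count types — with flooring at zero and
capping methylated at coverage so normalized β stays in [0, 1].  Cells
whose scaled coverage is non-positive are dropped with a log entry.

NMDS minimizes Kruskal stress-1 by SMACOF majorization alternating with
isotonic regression of configuration distances on the dissimilarity rank
order; disparities are rescaled each iteration so the stress denominator
is configuration-invariant.  Defaults: 20 random restarts, tolerance
1e-7 on stress, seed exposed everywhere.  Stress is non-increasing across
iterations (a tested property) and exactly embeddable configurations
reach stress < 1e-4.

PERMANOVA uses Anderson's pseudo-F computed from the Gower-centered
squared-distance matrix; p = (1 + #{F_perm ≥ F_obs}) / (n_perm + 1) over
random label permutations, or exact enumeration of all permutations for
small designs.  Pairwise contrasts re-run the test on sample subsets and
are reported unadjusted (an adjustment flag exists).  PERMDISP embeds the
distance matrix by principal coordinates, keeps negative-eigenvalue axes
on the imaginary part (squared centroid distances are real-part minus
imaginary-part contributions, floored at zero), computes each sample's
distance to its group centroid (centroids, not spatial medians; no bias
adjustment), and compares groups by one-way ANOVA plus Tukey HSD.
Singleton groups get distance 0 and are flagged.  Distances are Euclidean
only, matching the normalized-β geometry.

## Mutation context

Variants are annotated with the five flanking nucleotides on each side
(circular wrap at the origin; the stated reference allele is validated
against the genome).  GATC gain/loss is decided by counting motif
occurrences overlapping the variant in the reference vs alternate
windows; since the 4-bp motif is shorter than the 5-bp flank, the
windowed count provably equals a whole-genome recount, and the test suite
checks that equivalence against the simulator's recount-based truth
labels.  Multi-allelic records are decomposed per allele; indels are
handled by recounting in the flank+allele+flank window with net
gain/loss.  Per-background GATC-mutation percentages are reported to one
decimal with a bootstrap 95% percentile CI (default B = 10,000, seeded).
The resampling unit is the individual mutation within a background; with
clones pooled this converges to the binomial interval (a tested
property).  Other units (e.g. clone-level resampling) give narrower
intervals and are configurable, so no single CI is canonical.

## The simulator

Baseline per-adenine methylation is a mixture: weight 0.97 on
Beta(mc, (1−m)c) with m = 0.97, c = 60 (median ≈ 0.975), and weight 0.03
on a broad hypomethylated component 0.60·Beta(2, 2) — the scale of
hypomethylation seen in a healthy Dam methylome, where a few percent of
adenines sit below 0.60.  Coverage is negative-binomial (gamma-Poisson)
with mean 57 and size 20 (median ≈ 56); methylated counts are binomial.
Epimutational drift is Normal noise on logit(β) per site per sample with
a group-specific sd — 0.1 for stable groups and 0.4 (4×) for the
high-drift condition — so perturbed values stay in (0, 1) by
construction.  Differential sites receive a fixed β shift (default −0.3,
hypomethylation being the dominant observed direction) in treatment
groups, injected only where the shifted value stays inside (0.01, 0.99).
All draws derive from one seed; identical configs are byte-identical.

What the simulator does *not* emulate: sequence-context-dependent
miscalling, read-level correlation (each read is an independent
Bernoulli), strand-linked baseline correlation within a palindrome,
replication-timing gradients in coverage, and cell-to-cell
heterogeneity.  Passing the recovery and calibration tests therefore
demonstrates that the pipeline's statistics behave correctly under the
stated model, not that any particular methylation caller's error profile
is handled.

## Problem sizes and determinism

The calibration, recovery and drift studies run at 2,000 adenines with
3–4 samples per group — enough for stable rates while keeping the full
test suite and the acceptance script fast.  The calibration study is run
at a baseline β of 0.9 with drift 0, i.e. under the binomial null the
test assumes, which is where a uniformity check of raw p-values is
meaningful (see the calibration caveats above for the saturated regime).
The drift study uses 3 ancestor + 4 + 4 samples, matching a typical
clone-resequencing design.  Permutation tests use 999 permutations;
NMDS uses 4 restarts inside the batch studies and 20 by default.  Every
stochastic routine takes an explicit seed, and the CLI writes a manifest
(inputs, checksums, seed, version) next to every output.

## Known limitations

* No overdispersion-aware (beta-binomial) differential test; replicate
  heterogeneity beyond binomial shows up as anticonservative raw
  p-values and is controlled in practice by the effect-size cutoff.
* The SLIM π₀ estimator is a faithful-in-spirit sliding-linear-model
  implementation, not a line-by-line port of any published code; BH is
  the conservative default for short inputs.
* Promoter smoothing is a running median, not penalized quantile
  regression.
* The genome-census check against the K-12 chromosome requires a network
  fetch of U00096.3; everything else is self-contained.
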