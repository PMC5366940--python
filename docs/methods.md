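# Methods

This note documents the models, algorithms and defaults implemented in
`methylsex`, the assumptions behind them, and what the synthetic cohort
does and does not emulate.

## Data model and filtering

The atomic measurement is a cytosine call: chromosome, position
(0-based internally; the Bismark coverage and cytosine-report dialects
are 1-based and converted only at the I/O boundary), strand, context
(CG/CHG/CHH) and methylated/unmethylated read counts.  The methylation
level of a cytosine is `#Cs/(#Cs + #Ts)`; at zero coverage it is
*undefined* (NaN), never 0, so downstream averages are not biased
toward hypomethylation.  Pre-filtering keeps calls with coverage
strictly greater than 10 reads, and every analysis runs per context.
CpG dyads are kept per strand by default; an optional symmetric-CpG
merge (summing the two strands of a dyad) is provided but off, since
merging halves positional resolution and the per-strand treatment is
the more conservative default.

## Differential methylation

Each site is tested with the binomial-GLM likelihood-ratio test of
methylation proportion on group membership, with per-sample binomial
totals.  The design holds a single two-level factor, so the maximum
likelihood estimate is the pooled per-group proportion and the deviance
difference between the group model and the intercept-only model has a
closed form: the G-statistic of the pooled 2×2 group × state table,

    G = 2 Σ O ln(O/E),   p = P(χ²₁ ≥ G).

The implementation evaluates this closed form, vectorised over sites;
tests verify it against an independent G-test implementation to 1e-9.
Statistics below 1e-10 are clamped to zero so exactly equal pooled
proportions give p = 1.  Multiple testing uses Benjamini–Hochberg
(assumption-light and reproducible; some methylation toolkits default
to SLIM q-values instead — a deliberate divergence).  A site is a DMC
when q < 0.001 **and** the pooled difference is at least 25 percentage
points; a 20 pp variant is shipped as the `figure1` preset because both
effect-size cutoffs are in common use.  Sites are testable only when
each group retains ≥ 2 covered samples, guarding against single-sample
artifacts.  No overdispersion correction is applied in the test; its
type-I calibration is therefore checked on binomial nulls, while the
simulator deliberately generates beta-binomial (overdispersed) data so
that end-to-end results do not depend on the test being exactly
calibrated.  The two gardens are pooled in the test by default (the
patterns the analysis targets are constitutive across sites); no
covariate adjustment or DMR segmentation is attempted.

Gene-feature profiles report, per sex and per feature (promoter, exons,
introns; numbering follows transcription direction), the
coverage-weighted mean methylation Σmeth/Σtotal over covered sites plus
the count of overlapping significant DMCs.  Candidate genes are ranked
by overlapping significant-DMC count, ties broken by the largest
absolute difference, then gene id.  The promoter is a fixed 2000 bp
window upstream of the TSS (configurable; the underlying biology offers
no crisp boundary).

## Tile features

Methylation is summarized in non-overlapping 500 bp genome tiles; a
tile's value for a sample is Σmeth/Σcoverage over covered cytosines in
the tile and it counts as *detected* when at least one covered cytosine
remains after the coverage filter (`min_sites` is configurable).
Feature filtering first keeps tiles detected in ≥ 80 % of samples, then
— among those — tiles whose across-sample IQR strictly exceeds the
median IQR of the detection-passing set (so roughly the more variable
half survives).  Residual missing entries are replaced by the feature's
across-sample median, which stays inside the observed range and [0,1];
the detection mask is retained for audit.

## Penalized logistic regression with supervised clustering

The classifier builds *meta-features*: ordered clusters of oriented,
standardized tiles whose arithmetic mean (centroid) is one predictor in
a logistic model.  The criterion is the ℓ₂-penalized negative
log-likelihood

    J(β) = −Σᵢ [yᵢ ln μᵢ + (1−yᵢ) ln(1−μᵢ)] + λ Σ_{k≥1} βₖ²

with the intercept unpenalized and λ = 1/32 by default.  Clusters are
grown greedily: every candidate tile is tried in both orientations
(+x, −x; methylation can be hyper- or hypomethylated in either sex),
all coefficients are refitted for each candidate, and the single best
addition is accepted iff it lowers J by more than 1e-12 (the strict
tolerance prevents add/prune cycling).  After each accepted addition a
pruning pass removes the member whose removal most lowers J, if any
strictly does.  Earlier clusters' centroids remain in the model as
covariates with refitted coefficients.  Up to q = 10 clusters are
built, stopping early when a new cluster cannot improve J; clusters are
capped at 15 members (the observed sizes are far smaller).  A feature
may serve in several clusters; within a cluster ids are unique, and
appending a value-duplicate of a singleton's member leaves the centroid
unchanged — a tie, therefore rejected.

Coefficients are fitted by Newton/IRLS with step-halving, converged at
penalized-gradient max-norm < 1e-8 (limit 100 iterations;
non-convergence is flagged and the last iterate returned).  Candidate
scans run batched across all candidates to a 1e-6 scan tolerance; the
accepted candidate is then refitted to full tolerance, so every greedy
decision rests on an exactly minimized criterion.  All tie-breaks are
deterministic: features are sorted by id at fit time and the first
best-scoring candidate wins, positive orientation preferred.  Test
samples are always standardized with the training means and SDs.
Interpretation note: the reference configuration this default mirrors
pairs q = 10 with ~60 selected features at ~6 per cluster; q is read
here as the number of clusters, consistent with that arithmetic.

Greedy forward selection is a local search: on some instances no
forward path reaches the globally best small cluster.  The test suite
therefore checks exactness against exhaustive enumeration on instances
where an oracle (pure forward selection scored by exhaustive refits)
confirms the optimum is forward-reachable, and separately checks that
the greedy criterion never exceeds the null model's.

## Cross-validation, recurrence and prevalence

Samples are split 70/30 into training and test at the genotype level
(clones never straddle the split), stratified by sex.  The training set
is cross-validated with K = 5 folds × R = 50 iterations; folds are
stratified by sex and, under the default `by-genotype` strategy, keep
all clones of a genotype together (`fully-random` is the alternative).
Each iteration reshuffles with a seed derived from (seed, iteration);
draws whose training splits are single-class are redrawn (≤ 100
attempts).  Misclassification is reported both pooled over all held-out
predictions and as the mean per-fit rate (the two can differ when folds
are unequal).

A feature's recurrence frequency is the fraction of the K×R fits that
selected it into any cluster (once per fit, even if it serves several
clusters); bins are F4 > 0.80, F3 ∈ (0.20, 0.80], F2 ∈ (0.10, 0.20],
F1 ≤ 0.10.  Per chromosome, *relative cluster prevalence* is the
chromosome's share of all selections across fits divided by its share
of input features — under uniform selection every chromosome sits near
1, and values ≫ 1 mark concentrated predictive signal.  "Share of input
features" operationalizes the minimal expectation against which
prevalence is measured; total and unique per-fit feature counts are
both reported since a feature can join several clusters.  The final
model is refitted on the full training set and evaluated once on the
held-out test samples, with the 2-D centroid projection (predictors 1
and 2) emitted for the discrimination plot.

## Synthetic cohort

The generator emulates the study design the analysis assumes, at desk
scale: 19 chromosomes of 80 kb each (~24 cytosine site events per kb;
CG events emit both strands of the dyad), two genes per chromosome and
a 13-gene panel on the last chromosome, whose middle gene is the
planted sex-linked gene.  The default cohort is 9 female + 11 male
genotypes, each cloned at two gardens (40 samples).  Coverage per site
is negative-binomial (mean 30, size 10), so the >10× filter removes a
small, realistic minority of calls.  Methylated counts are
beta-binomial (dispersion ρ = 0.05) around an effect level adjusted on
the logit scale by a genotype random effect (SD 0.3) and a fixed garden
effect (0.2); levels of exactly 0 or 1 stay degenerate.  Background
levels are CG 0.30, CHG 0.25, CHH 0.10; the planted gene carries a
male-biased promoter (0.65 vs 0.15) and intron 1 (0.70 vs 0.10), an
intron 4 at 0.90 in both sexes and an intron 5 at 0.02; five weak
male-biased CG tiles (Δ = 0.15) are scattered off the SDR chromosome to
mimic the faint genome-wide sex signal.  The within-sex variance
components (genotype vs garden) are not empirically constrained;
the defaults are plausible placeholders exposed in `CohortSpec`.

What the simulator does **not** emulate: read-level data (no FASTQ,
alignment or bisulfite-conversion error), linkage between neighbouring
cytosines beyond shared effect regions, genome-scale feature counts
(≈3,000 tiles rather than ≈243,000), or real annotation complexity.
Passing tests therefore demonstrate that the *pipeline* recovers the
structure it assumes from data of this shape — not that real WGBS data
possess that structure.  One consequence of the reduced feature count
is documented honestly in the test suite: with ~1,500 candidate tiles
and 40 samples, the best noise-correlated tile is selected in most CV
fits even under permuted labels, so a permutation null is not
guaranteed to be free of high-recurrence (F4) features at this scale,
whereas label-permuted misclassification does sit at chance.

## Problem sizes and runtime

Defaults were chosen so the full pipeline runs in minutes on a single
core: the bundled acceptance script uses R = 10 CV iterations (the
library default stays R = 50) and records both values in its output;
unit tests use smaller cohorts.  Determinism is end-to-end: a single
seed fixes the genome, the cohort, every fold draw and every fit, and
identical seeds produce byte-identical fixture files and reports.
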