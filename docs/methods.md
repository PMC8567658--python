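# Methods

This note documents the statistical models implemented in `musclemeth`, the
choices made where the design was genuinely open, what the synthetic-data
generator does and does not emulate, and the package's known limitations.
All quantitative statements here are computed by the test suite or by
`scripts/acceptance.py`; nothing is asserted that the code does not measure.

## Modelling scale and conventions

Statistics are computed on beta values (methylated fraction in [0, 1])
directly, so effect sizes are mean methylation differences in proportion
units (x100 for percentage points).  An M-value (logit2) mode is available
through `core_io.beta_to_m` for users who prefer variance-stabilised
modelling; it is not the default because the headline effect-size unit of
this analysis is the percentage methylation difference.  Logit transforms
clip beta to [1e-6, 1 - 1e-6].

Sex is coded F = 0, M = 1: positive effects mean hypermethylated in males.
Manifest positions are 1-based points; all interval files (chromatin
states, TFBS) are BED dialect, 0-based half-open, and a CpG at 1-based
position p overlaps [s, e) iff s <= p - 1 < e.  A probe annotated to
several genes contributes to each of them, matching array gene-set-testing
practice.

## Per-cohort EWAS

Each CpG is fitted by OLS against an intercept, sex, and the cohort's
declared covariates.  Interaction designs (`sex*timepoint`) report the sex
main effect at the reference timepoint; a flag to average over timepoints
instead is available by passing the appropriate contrast terms.  Repeated
measures are collapsed by averaging within subject x condition cells before
fitting.  This is a deliberate simplification of consensus-correlation
(duplicate-correlation) blocking: it forfeits a little efficiency but keeps
the sex effect unbiased and avoids re-implementing REML, and its null
calibration is verified directly (uniform p-values on synthetic nulls).
Missing numeric covariates are imputed by the within-sex mean and flagged;
this replaces chained-equation imputation, which in the motivating use case
affected only a handful of individuals.

Variance moderation follows the standard empirical-Bayes scheme: with
per-probe residual variances s^2 on d degrees of freedom, the prior
(d0, s0^2) is estimated by matching the mean and variance of
log s^2 - digamma(d/2) + log(d/2) to the scaled-F model (the trigamma
inverse solved by Newton iteration); the posterior variance is
(d0 s0^2 + d s^2)/(d0 + d) and moderated t statistics are referred to
t(d0 + d).  Degenerate inputs: zero-variance probes are flagged, excluded
from hyperparameter estimation and assigned p = 1; when the observed log
variances are under-dispersed relative to pure sampling noise (evar <= 0),
d0 is infinite and the shrinkage target is the geometric mean variance, so
identical sample variances are an exact fixed point.  Hyperparameter
recovery is tested at 50k probes (d0 within 20%, s0^2 within 10%).

Cohort-characteristic comparisons use Welch's t for continuous covariates
and a two-sided Fisher exact test for binary ones.  The Fisher choice for
the 2x2 sex-by-disease table is deliberate even where source tables label
all rows as t-tests; an exact test is the defensible option at these counts.

## Empirical-null calibration

EWAS z-scores are decomposed as p0 N(mu, sigma^2) + p+ N(mu+, s+^2) +
p- N(mu-, s-^2), the null component carrying the bias (mu) and inflation
(sigma) induced by unmeasured confounding.  The original empirical-null
tool in this space samples the posterior by Gibbs; this package instead
fits the mixture by EM with deterministic initialisation (null mean =
median, null sd = 1.4826 x MAD, signal components at +-3 sd, p0 = 0.8) so
results are exactly reproducible.  Tolerance: 1e-6 relative change in
log-likelihood, max 1000 iterations; non-convergence falls back to the
median/MAD estimator with a warning.

Two constraints are part of the model, not tuning: signal-component means
must stay at least 2 null-sd away from the null mean, and signal sds must
be at least 1.25x the null sd.  Without them the EM's signal components
absorb the null's own tails (on pure N(0,1) data the estimated inflation
drops to ~0.95), which would make calibrated p-values anti-conservative.
With them, the estimator recovers (mu, sigma) = (0, 1) on standard-normal
scores within +-0.03, and on a 1.5-inflated, 0.2-biased null with 5%
positive signal recovers sigma within +-0.08 and mu within +-0.05, with
post-correction lambda_gc of the true-null fraction inside [0.95, 1.05].

Calibrated scores are z' = (z - mu)/sigma with p' = 2 Phi(-|z'|); the
calibrated standard error is derived as effect/z' (rather than scaling se
directly) so that meta-analysis weights reflect calibrated precision while
effects keep their physical units.  z' = 0 yields infinite se (zero
weight).

## Meta-analysis, DMPs, PCA

Fixed-effects inverse-variance weighting assumes one true effect shared by
the cohorts; Cochran's Q is referred to chi-square(k-1) and I^2 > 50% flags
(but does not remove) heterogeneous probes.  Only CpGs present in at least
two cohorts are combined, which lets a small legacy array contribute
without restricting the meta-analysis to its probe set.  BH adjustment uses
a stable sort on (p, probe id) so ties are reproducible; DMPs are called at
FDR < 0.005.  The variance-explained-by-sex summary runs PCA per cohort on
the standardized sample x DMP matrix, picks the PC (of the first five) with
the largest absolute point-biserial correlation with sex — a deterministic
stand-in for "the PC that visually separates the sexes" — and reports the
adjusted R^2 of PC ~ sex.

## DMR calling

Squared meta z-scores are smoothed along each chromosome with a Gaussian
kernel (sigma = lambda/C; defaults lambda = 1000 bp, C = 2; kernel
truncated at 3 sigma for linear-time scanning — an approximation that
changes weights by < e^-4.5).  Under the null the smoothed statistic
Y = sum(w~ z^2) is approximated by Satterthwaite moment matching as
c chi-square(nu) with c = sum(w~^2), nu = 1/c.  This two-moment null is the
declared construction; its marginal calibration is verified on independent
per-cluster representatives (kernel smoothing makes *neighbouring* smoothed
p-values strongly dependent, so a raw KS test across all CpGs is not a
valid uniformity check and is not used).  Significant CpGs (BH on smoothed
p, fdr < 0.005) within lambda of each other merge into regions of at least
2 CpGs; region boundaries are the min/max member positions.

Region statistics: Stouffer combines member signed z derived from member
FDR (z_i = sign(effect_i) Phi^-1(1 - fdr_i/2), z_bar = sum z_i / sqrt(k));
Fisher combines member meta p as -2 sum ln p ~ chi-square(2k); HMFDR is the
harmonic mean of member FDRs.  All three are reported on the p-scale, the
column naming makes that explicit, and a region is significant only when
all three fall below 0.005.  Mixed-sign regions are allowed (the signed
Stouffer penalises them).  Acceptance is by planted-region recovery and
null calibration, not bitwise parity with any particular regional-analysis
package whose internal variance model is version-dependent.

## Enrichment

Context tests are r x c chi-squares of DMP status (hyper/hypo/non) against
a genomic category.  Raw Pearson residuals (whose squares sum to the
chi-square) and adjusted standardized residuals (approximately N(0,1) per
cell) are both reported; cells with |adjusted residual| > 4 are flagged as
driving the association — the threshold is configurable since the
convention behind "greater contribution" markers varies.  Probes annotated
to two different chromatin states are excluded before state enrichment.

The sex-discordant-state odds ratio is oriented as (non-DMP odds of a
discordant state)/(DMP odds), so values below 1 mean DMPs are
over-represented in discordant states; the 95% CI is Woolf's logit interval
with Haldane–Anscombe correction on zero cells (CI only).

Gene-set tests correct for probe-number bias: genes covered by more probes
are more likely to contain a significant probe by chance.  The Monte-Carlo
mode (default in tests) draws gene sets of the observed significant-gene
count with probability proportional to probe count via Gumbel top-k (a
vectorised exact sampler for sequential weighted draws without
replacement) and reports p = (1 + #{overlap >= observed})/(n_iter + 1).
The Wallenius mode uses scipy's noncentral hypergeometric tail with odds =
mean probe count in set / out of set.  The Monte-Carlo p is validated
against exhaustive enumeration on a six-gene universe.

TFBS enrichment is a per-dataset one-sided Fisher test of DMPs versus the
tested-CpG background, reported unadjusted (interval datasets are heavily
dependent, so FDR assumptions fail) and ranked by -log10 p.  External
CpG-list overlaps are tested by uniform resampling from the array universe
with the (1 + b)/(1 + n) estimator, which cannot return p = 0.

## Expression integration

DMG/DEG overlaps are computed on uppercased gene symbols; enrichment of a
DEG list among the methylation hits reuses the bias-aware gene-set test.
Quadrant concordance pairs each promoter- or enhancer-class DMR (a region
belongs to a class when any member CpG lies in a promoter- or
enhancer-type chromatin state; a region may belong to both) with its
genes' expression effects; the inverse fraction is the share of pairs with
opposite effect signs, and the permutation null shuffles methylation
effects across pairs within each region class (the within-class choice is
the declared resolution of an ambiguity; a global shuffle would mix
promoter and enhancer effect-size distributions).  Note that with strongly
one-directional methylation effects the sign margins alone produce high
inverse fractions under permutation — the test measures pairing-specific
coupling beyond the margins, which is the question actually at issue.

qPCR fold changes use 2^-ddCt: per-sample dCt against the mean Ct of the
housekeepers (arithmetic mean of Ct = geometric mean on the expression
scale), triplicates with sd > 1 Ct excluded, Welch's t on dCt, and
housekeeper selection by lowest variance of per-sample mean Ct (a
transparent stand-in for multi-algorithm stability ranking).

## Fibre-type mediation and hormones

Fibre-type proportion is a downstream effect of sex, not a confounder, so
it is never added to a mixed-sex model.  Each cohort is split by sex,
methylation is regressed on type-I proportion (plus the cohort's non-sex
covariates) within each single-sex group — the group EWAS goes through the
same moderation and empirical-null calibration as the main analysis — the
groups are combined by the same IVW machinery, and BH adjustment is
restricted to the sex-DMP set.  The reported quantity is the fraction of
sex-DMPs associated with fibre proportion at FDR < 0.005; a planted 15%
share is recovered within +-5 percentage points at 150 samples/cohort.
Groups under 10 samples are excluded with a warning.

Beta regression for proportions uses a logit mean link with constant
precision phi, maximised by BFGS with the analytic score (the steep
likelihood at very large phi defeats finite-difference gradients);
boundary observations are shrunk by the Smithson–Verkuilen transform
y' = (y(n-1) + 0.5)/n, Wald tests come from the inverse observed
information (finite differences of the analytic score), and convergence on
steep surfaces is judged by the score scaled by the log-likelihood
magnitude.  Calibration: sex-coefficient recovery within +-0.1 and ~95%
Wald-CI coverage over 200 replicates at n = 200, phi = 30.

Hormone scans regress methylation on one hormone (or the first two PCs of
a standardized log hormone panel) within one sex; hormones track sex so a
mixed-sex scan would be confounded by construction.  The free androgen
index is T x 100/SHBG.  Free testosterone solves the mass-action
equilibrium with saturable SHBG and albumin binding — a cubic in the free
concentration with a unique positive root — using association constants
K_SHBG = 1.0e9 L/mol, K_albumin = 3.6e4 L/mol and default albumin
4.3 g/dL (standard literature values, configurable); the closed-form root
is verified against fixed-point iteration of the binding equations to
1e-10 relative tolerance.

## The synthetic generator

Signal is composed on the logit2 scale and mapped through the inverse
logit: per-probe bimodal baselines, a sex effect sized to produce the
target delta-beta at baseline 0.5, a fibre effect proportional to the
sample's type-I proportion, batch offsets (sd 0.05), subject random
intercepts (sd 0.10, shared across repeated measures), and residual noise
(sd 0.25) with a within-cluster shared component (fraction 0.5).  Probes
sit in clusters of 8 spanning <= 1000 bp with inter-cluster gaps of 10x
that, so planted sex effects (assigned to whole clusters, one sign per
cluster with P(hypo) = 0.94) form recoverable regions and the >3
correlation-length independence property holds across clusters.  Default
effect sizes are exponential with mean |delta-beta| 0.028 (hyper) and
0.035 (hypo).  Type-I fibre proportions are Beta-distributed with female
mean 0.52, male mean 0.42, precision 30 — source studies report the
direction but not the values; these defaults create a detectable but
realistic mediator.  One cohort can be restricted to every 20th probe to
emulate a legacy small array.  Hormone panels are log-normal with
sex-specific geometric means and are independent of methylation by
construction, so hormone scans on them are genuine nulls.

Not emulated: probe-chemistry (type I/II) noise structure, cell-type
heterogeneity, meQTL/CNV effects, and array-specific detection failure
patterns.  Passing tests therefore demonstrate the statistical machinery's
calibration and power under the planted model, not robustness to raw-array
artefacts — pre-processing (normalisation, batch correction at the matrix
level) is explicitly upstream of this package, which consumes normalized
beta matrices.

## Problem sizes and numerical choices

The test suite and acceptance script run the full pipeline at 20k probes
and 24–200 samples per cohort, 25 replicates for null calibration, 10k (or
more) iterations for permutation/resampling p-values where the answer is
frozen, and fewer where only reproducibility is being checked.  These
sizes were chosen to make every property measurable with comfortable
statistical margins on a single CPU; all of them are parameters, and the
same code runs at full array scale (850k probes) unchanged.

Known limitations: within-cell averaging is less efficient than
consensus-correlation blocking when repeat counts are unbalanced; the
Satterthwaite DMR null ignores inter-CpG correlation of the *scores*
(regions are gated by three combined statistics and validated by null
calibration instead); the EM empirical null assumes approximately Gaussian
signal components; and the Wallenius gene-set mode conditions on a single
odds parameter rather than per-gene weights (the Monte-Carlo mode does
not).
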