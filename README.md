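# musclemeth

Sex-differential DNA methylation analysis for human skeletal muscle, built as
a reusable Python library.  Skeletal muscle is one of the most sexually
dimorphic human tissues; epigenome-wide association studies (EWAS) of sex ask
which CpG sites differ in methylation between males and females, and whether
those differences are explained by fibre-type composition, circulating sex
hormones, or chromatin context.  `musclemeth` implements the complete
inference chain for a multi-cohort study of this question, together with a
seeded synthetic-cohort generator with planted ground truth so that every
stage can be exercised and validated without access to restricted cohort
data.

Intended users: methylation-array analysts who want a transparent,
fully-tested reference implementation of the EWAS-meta-analysis stack, and
methods people who want calibrated synthetic benchmarks for it.

## The statistical pipeline

1. **Per-cohort EWAS** (`musclemeth.ewas`) — per-CpG ordinary least squares
   of beta values on sex plus cohort covariates (`DNAm ~ sex + age + batch`,
   interaction designs like `sex*timepoint` supported), with empirical-Bayes
   variance moderation: the prior `(d0, s0^2)` is estimated by matching
   moments of log sample variances to a scaled-F model, the posterior
   variance is `s^2_post = (d0 s0^2 + d s^2)/(d0 + d)` and moderated t
   statistics are referred to `t(d0 + d)`.  Repeated measures are collapsed
   by within-subject averaging; sex is coded F=0, M=1 so a positive effect
   means hypermethylated in males.

2. **Empirical-null calibration** (`musclemeth.calibrate_meta`) — per-cohort
   z-scores are modelled as a three-component Gaussian mixture
   `p0 N(mu, sigma^2) + p+ N(mu+, s+^2) + p- N(mu-, s-^2)` fitted by
   constrained EM with deterministic initialisation; the null component's
   `mu` (bias) and `sigma` (inflation) recalibrate the scores:
   `z' = (z - mu)/sigma`.

3. **Fixed-effects IVW meta-analysis** — weights `w_i = 1/se_i^2`, combined
   effect `sum(w b)/sum(w)`, `se = sum(w)^{-1/2}`, Cochran's Q and
   `I^2 = max(0, (Q - (k-1))/Q) x 100`, restricted to CpGs present in at
   least two cohorts; Benjamini–Hochberg FDR with DMPs called at FDR < 0.005.

4. **DMR calling** (`musclemeth.dmr`) — Gaussian-kernel smoothing of squared
   z-scores along each chromosome (bandwidth sigma = lambda/C, defaults
   lambda = 1000 bp, C = 2), a Satterthwaite scaled-chi-square null, and
   merging of significant CpGs within lambda into regions scored by
   Stouffer, Fisher and harmonic-mean-FDR statistics (all three < 0.005 for
   significance).

5. **Enrichment** (`musclemeth.enrichment`) — chi-square tests of DMP status
   against chromatin states and CpG-island relation with standardized
   residual flagging; Fisher odds ratios for sex-discordant chromatin
   states; one-sided Fisher TFBS enrichment against the tested-CpG
   background; and gene-set tests that correct for probe-number bias
   (Wallenius noncentral hypergeometric, or weighted Monte-Carlo sampling).

6. **Expression integration** (`musclemeth.integrate`) — DMG x DEG overlap
   with bias-aware enrichment, promoter/enhancer quadrant concordance with a
   permutation null (methylation effects shuffled within region class), and
   qPCR fold changes by 2^-ddCt with housekeeper normalisation.

7. **Mediation and hormones** (`musclemeth.mediation`) — sex-stratified
   meta-analysis of methylation on type-I fibre proportion (FDR restricted
   to the sex-DMPs), maximum-likelihood beta regression of fibre proportion
   on sex, MYH7/(MYH7+MYH2+MYH1) fibre estimation from RNA-seq TPMs,
   single-sex hormone scans, the free androgen index and mass-action
   (Södergård) free testosterone.

8. **Synthetic cohorts** (`musclemeth.synthgen`) — 2–4 cohorts of beta values
   with probes in correlated clusters on a synthetic genome, predominantly
   one-directional sex effects (94% hypomethylated in males, mean
   |delta-beta| 2.8%/3.5%), fibre-type-mediated effects, batch and subject
   random effects, repeated measures, partial probe overlap (one
   small-array cohort), plus coupled expression tables and null hormone
   panels.  Fully determined by one seed.

## Worked example

```bash
python examples/01_simulate_and_meta_analysis.py
```

prints (exact numbers; the run is fully seeded):

```
cohorts: [('cohort1', 8000, 100), ('cohort2', 8000, 60), ('cohort3', 400, 24)]

DMPs at FDR<0.005: 352 of 8000 tested CpGs
  hypomethylated in males: 98.3%  (mean delta-beta -3.78%)
  hypermethylated in males: 6  (mean delta-beta 4.42%)
  cohort1: bias=-0.061 inflation=1.032 lambda_gc=1.25
  cohort2: bias=-0.046 inflation=1.005 lambda_gc=1.17
  cohort3: bias=-0.075 inflation=1.038 lambda_gc=1.34
  cohort1: PC1 separates the sexes, adjusted R^2 = 0.99
  cohort2: PC1 separates the sexes, adjusted R^2 = 0.99
  cohort3: PC1 separates the sexes, adjusted R^2 = 0.92

recovery of planted sex-CpGs: 43.8% sensitivity, observed FDR 0.0057
```

Reading this: 352 CpGs were called differentially methylated between the
sexes at FDR < 0.005, almost all hypomethylated in males, matching how the
effects were planted; per-cohort bias/inflation estimates are close to
(0, 1) after the planted signal is accounted for; the first principal
component of the methylation at the DMPs separates the sexes almost
perfectly within each cohort; and at the generator's realistic (small)
effect sizes roughly half of the planted CpGs reach genome-wide
significance while the observed false-discovery proportion stays at the
nominal level.  The other `examples/` scripts walk through DMR calling,
context/TFBS/gene-set enrichment, expression integration with the
permutation null, and the fibre-mediation and hormone analyses.

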