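# Methods

## Scope and model

`mrmediate` implements two-sample Mendelian randomization (MR) from GWAS
summary statistics, the usual MR sensitivity battery, and two-step MR
mediation. Two-sample MR treats SNPs as instrumental variables: each
instrument must be associated with the exposure, independent of confounders
of the exposure–outcome relation, and affect the outcome only through the
exposure. Under those assumptions the per-SNP Wald ratio β̂_Yj/β̂_Xj
estimates the causal effect, and the estimators in `mr_core` are different
ways of pooling the ratios that trade efficiency against robustness to
invalid instruments.

All causal effects are linear on the scale of the outcome betas; for a
case-control outcome that scale is the log-odds, and results are also
reported as odds ratios with exponentiated confidence limits.

## Instrument selection

- p-value threshold: strict inequality `pval < threshold`. Defaults: 1e-5
  for forward analyses of sub-genome-wide exposure panels, 5e-8 for reverse
  MR. The threshold is applied before clumping; clumping then prunes within
  the surviving set (the conventional order — the alternative order can only
  differ when a weaker SNP shadows a stronger one across the threshold).
- Clumping: greedy by ascending p-value, ties broken lexicographically by
  variant id so the output is a deterministic function of the input. In
  `matrix` mode a candidate is rejected when its pairwise r² with any
  accepted SNP within the window (default 10,000 kb, same chromosome) is
  ≥ 0.001; missing LD entries count as independence, and SNPs lacking
  positions are compared unconditionally. `distance_only` mode keeps at most
  one SNP per window and needs chrom/pos. No reference panel is bundled: LD
  enters only through a user-supplied pairwise r² lookup, which keeps the
  algorithm testable and the interface explicit about where LD information
  comes from.
- Strength: per-SNP variance explained R² = β²·EAF·(1−EAF)/(SE²·N) and
  F = ((N−K−1)/K)·R²/(1−R²). Screening uses per-SNP F (K = 1) with the
  strict rule F > 10, because screening happens before the final instrument
  count is known; set-level metrics are available from
  `instruments.instrument_metrics`.
- Power: for a binary outcome the causal log-odds estimate has SE roughly
  (n·R²·v(1−v))^(−1/2) for outcome sample size n and case fraction v, giving
  non-centrality n·R²·v(1−v)·ln(OR)² and the two-sided normal-approximation
  power. This parameterization makes power exactly alpha at OR = 1 or
  R² = 0 and monotone in n, R² and |ln OR|.

## Harmonization

Matching is by variant id only (the intended data sources share rsIDs; no
positional fallback). Resolution order per SNP: palindromic check, direct
allele match, swapped match (flip: negate the outcome beta, complement the
outcome EAF), strand-complement then direct/swapped, otherwise incompatible.
Palindromic (A/T, C/G) SNPs are dropped unconditionally by default — the
conservative reading of "eliminate palindromic SNPs" — with an optional
frequency-window mode (`drop_all_palindromic=False`) that drops them only
when either EAF lies in [0.42, 0.58] and aligns the rest by minor-allele
agreement. Every input SNP yields a record with an action (kept / flipped /
dropped) and, iff dropped, a reason, so counts are conserved and the report
is auditable.

## Estimators

- IVW fixed vs random: both are computed; pipeline and mediation legs follow
  the heterogeneity-guided rule — fixed effects unless the IVW Cochran Q has
  p ≤ .05, then the multiplicative random-effects SE (inflation
  max(1, √(Q/(J−1)))). Besides genuine pleiotropic heterogeneity, this
  inflation also absorbs the residual overdispersion from noise in the
  SNP-exposure betas, which the fixed-effect SE ignores.
- MR-Egger is fit after orienting every pair so β̂_Xj ≥ 0 (estimates must
  not depend on arbitrary allele coding); slope/intercept covariance uses a
  multiplicative dispersion factor max(1, Q/(J−2)).
- Weighted median: linearly interpolated weighted 50th percentile of the
  ratios with weights β̂_Xj²/σ_Yj²; SE by parametric bootstrap (default
  1000 replicates, explicit seed; pairs with β̂_Xj = 0 are excluded with a
  warning).
- Mode estimators: Gaussian-kernel density of the ratios (unweighted or
  inverse-variance weighted), bandwidth = factor × 0.9·min(sd, IQR/1.349)·
  J^(−1/5) (modified Silverman), argmax on a 512-point grid spanning the
  ratio range ± 3 bandwidths; degenerate spread returns the common ratio
  exactly. SE by parametric bootstrap.
- Wald ratio: single-instrument fallback with first-order SE |σ_Y/β̂_X|,
  labeled distinctly so downstream reports can flag it.

## Sensitivity battery

Cochran's Q sums squared standardized residuals about the IVW (df J−1) or
Egger (df J−2) fit, with an upper-tail chi-square p. The Egger intercept test
is two-sided normal. The pleiotropy residual-sum-and-outlier (MR-PRESSO
style) test compares the observed RSS about leave-one-out IVW predictions
with a parametric-bootstrap null (default 1000 draws; scaled down in tests),
runs per-SNP outlier tests with Bonferroni-adjusted empirical p-values, and,
when outliers are found, reports the outlier-removed estimate plus a
distortion p obtained by removing random same-size subsets of clean SNPs.
Empirical p-values use the (r+1)/(n+1) convention so none is exactly zero;
the distortion test is only reported when outliers exist. Leave-one-out
refits IVW omitting each SNP in turn.

## BWMR

The Bayesian-weighted model treats each instrument's true exposure effect as
latent, γ_j ~ N(0, σ₀²), with outcome effect β·γ_j plus a pleiotropic
deviation α_j ~ N(0, τ²); observed betas are Gaussian about the latents with
their reported SEs, and τ², σ₀² carry weakly-informative inverse-gamma
(1e-3, 1e-3) priors. Fitting is variational EM on a weighted evidence lower
bound: exact Gaussian E-step, closed-form M-step for β and σ₀², bounded 1-D
maximization for τ². Robustness comes from per-SNP weights
w_j = min(1, exp((c² − d_j²)/2)), c = 2, where d_j is the standardized
residual of β̂_Yj under the current fit's marginal — weight 1 for SNPs
within 2 SD, smoothly decaying beyond. Weights are recomputed between three
EM rounds and frozen within each round, so the recorded ELBO trace (final
round) is non-decreasing by EM monotonicity; convergence is a relative ELBO
change below 1e-6 (default), and non-convergence returns a flagged result
rather than raising. The SE of β comes from the numerical curvature of the
weighted marginal log-likelihood at the optimum.

## Mediation

`two_step_mediation` combines three independently estimated quantities:
total effect τ, exposure→mediator effect β₁ and mediator→outcome effect β₂.
Indirect = β₁β₂ exactly; direct = τ − β₁β₂ (the total is re-estimated, never
reconstructed); proportion = 100·β₁β₂/τ, undefined (with a warning) at
τ = 0. The delta variance is first-order, β₁²SE₂² + β₂²SE₁², with the
second-order term SE₁²SE₂² available by option — the first-order form is the
standard product-of-coefficients variance and the second-order term is
negligible at the instrument strengths where mediation is sensible. The
proportion CI applies the delta method to the ratio treating numerator and
denominator as independent; since the total and the product share estimation
noise this is an approximation, and it is labeled as such in the result.
`mediation_pipeline` runs the three MR legs (exposure instruments for the
total and β₁ legs, the mediator's own instruments for β₂) with the same
selection and harmonization rules throughout.

## Synthetic data generator

`simulate_triplet` emulates the structure of an immune-trait exposure GWAS
(default N = 3757), a circulating-protein mediator GWAS (N = 14,824) and a
case-control outcome GWAS (N = 160,589 with case fraction 1388/160,589),
under the linear structural model M = θ₁X, Y = θ₂M + θ_direct·X, so the
ground-truth total effect is exactly θ_direct + θ₁θ₂. Choices that matter:

- Effects are parameterized directly on the outcome's log-odds scale. The
  binary nature of the outcome enters through the effective sample size
  n·v(1−v) in the SE of the outcome betas — the small-effect approximation
  under which liability and log-odds parameterizations coincide up to a
  constant. This keeps the generator's truth on exactly the scale MR
  estimates, which is what calibration tests need.
- Per-allele SEs follow the standardized-trait approximation
  (2·N·maf·(1−maf))^(−1/2); MAFs are uniform on (0.05, 0.5) by default.
- True instrument effects are drawn Gaussian and rescaled so the summed
  variance explained hits the configured target exactly (default 0.08,
  giving mean per-SNP chi-square ≈ 10 at the default exposure N — the
  borderline-instrument regime of a small flow-cytometry GWAS; configs whose
  expected per-SNP chi-square falls below 1 are rejected as infeasible).
- The mediator (and optionally the outcome) gets its own disjoint instrument
  set: without mediator-specific instruments the mediator→outcome MR leg has
  no instruments and mediation cannot be estimated.
- Invalid instruments receive additive pleiotropic outcome effects
  (directional when the configured mean is nonzero); a configurable fraction
  of SNPs is palindromic; a configurable fraction of outcome rows is written
  allele-swapped, exercising harmonization end to end.
- p-values are computed from the generated beta/SE, so threshold logic runs
  on internally consistent statistics.
- `structure_seed` fixes the generative truth separately from the noise
  seed, producing independent cohorts of the same traits for validation
  studies; structure and noise streams use distinct seed-sequence keys so
  they remain independent even when the seeds coincide.
- Deliberately absent: LD between SNPs (clumping sees LD only via the
  optional lookup), individual-level genotypes, allele-frequency differences
  between cohorts, sample overlap, and winner's-curse-free three-sample
  designs. Passing calibration here therefore demonstrates correctness of
  the estimators under the stated model, not robustness to cross-ancestry
  frequency mismatch or LD misspecification in real data.

`simulate_screen_panel` instantiates many exposures (disjoint SNP sets, one
shared outcome) with a known causal subset, for testing screening power and
false-positive control. Per-exposure seeds derive from the panel seed.

## Pipeline

The full workflow is screen → multi-cohort validation → reverse MR →
mediation. An exposure is flagged when its headline IVW p < .05 and the
sensitivity battery raises no concern (all diagnostic p > .05); flagged
exposures are validated only when the IVW effect is significant with
consistent direction in every validation cohort; reverse MR re-runs the
estimator stack with outcome instruments at 5e-8 and reports "untestable"
when none exist. Mediation is attempted only for validated exposures whose
two mediation legs are both significant. Stages use unadjusted p < .05,
relying on multi-cohort replication for error control; Benjamini–Hochberg
q-values over the screen are reported for transparency but never used for
flagging. Per-exposure failures are logged and skipped; every threshold and
seed actually applied is written to the run log.

## Numerical and testing choices

- All stochastic procedures take explicit seeds and are reproducible
  bit-for-bit; bootstrap defaults (1000) are reduced in tests where only
  point estimates matter.
- Calibration and recovery tests use these problem sizes: 500 simulations
  for type-I calibration (30 instruments), 300 for mediation CI coverage
  (n = 50,000 per GWAS, total instrument R² = 0.2 — per-SNP F ≈ 300,
  i.e. unambiguously strong instruments, where the first-order delta CI is
  expected to hold its nominal level), 100 for planted-outlier detection
  (15 instruments, one SNP displaced exactly 5 outcome-SEs off the
  regression line, n_sim = 500), 200 for the PRESSO null-uniformity check
  (n_sim = 200).
- The planted outlier is displaced exactly 5 SEs from the regression line
  rather than having the offset added on top of its own sampling noise: with
  additive noise the realized displacement is 5 + z, z ~ N(0,1), and no
  calibrated detector can reach a high flag rate at this margin — the
  exact-displacement design measures the machinery, not the plant's luck.
- Weak-instrument (NOME) overdispersion is handled by the heterogeneity-
  guided random-effects rule rather than by explicit SIMEX-style correction;
  at the simulated instrument strengths the residual effect on CI coverage
  is within the tested tolerance.

## Known limitations

- No multivariable MR, Steiger filtering, radial MR, CAUSE or
  contamination-mixture estimators; one mediator at a time.
- LD clumping requires externally supplied r² (or positions for the
  distance-only fallback); there is no reference-panel reader.
- BWMR reports a variational point estimate with curvature SE, not a full
  posterior; the weight function and hyperpriors are fixed defaults exposed
  as parameters.
- The mediation proportion CI treats total and indirect estimates as
  independent, which understates their covariance when the same outcome
  cohort drives both.
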