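# Methods

This note documents the models implemented in `tauspread`, the synthetic
cohort they are exercised on, the numerical choices behind both, and what
the tests do and do not establish.

## Trajectory models

Regional tau accumulation is the slope of a linear mixed-effects model per
parcel: `SUVR_ij = (b0 + u0i) + (b1 + u1i)·t_ij + e_ij` with unstructured
random-effect covariance, fitted by REML.  Participant rates are
`b1 + EB(u1i)`, the empirical-Bayes (shrunken) slopes; with 2–4 visits the
shrinkage toward the group slope is substantial and intended.  The
optimizer is Powell (gradient methods frequently flag spurious
non-convergence when the random-slope variance is small); if Powell lands on
the zero-residual boundary — which happens for noise-free trajectories —
the fit is retried with BFGS and the converged interior solution is used.
Any remaining failure falls back to per-subject ordinary least squares,
flagged per parcel in the diagnostics sidecar.  Participants with fewer
than two visits get a missing slope, never zero.  MMSE slopes use the same
machinery with points/year units.

"Global" tau rate of change is the unweighted mean over a parcel subset
(default: all parcels); the subset is a configuration choice because no
canonical definition exists.

## Epicentre detection

Per region, baseline SUVR across participants is modelled as a
two-component univariate Gaussian mixture fitted by EM: means initialized
at the 25th/90th percentiles, equal initial weights and SDs, convergence
when the log-likelihood gain drops below 1e-6 (at most 500 iterations),
component SDs floored at 1e-3 of the data SD with up to 5 jittered restarts
on collapse, components relabelled so μ2 ≥ μ1.  The log-likelihood trace is
retained and its monotonicity asserted in the tests.

Two guards matter in practice:

* **One- vs two-component selection.**  A single Gaussian is also fitted
  and compared by BIC.  Regions where one component wins are flagged
  `unimodal` and scored 0 — without this, regions carrying only
  non-specific signal receive a spurious bulk/tail split whose "abnormal"
  posterior is near 1 for most participants, and cohort-mean scores at
  signal-free regions can exceed those at genuinely bimodal regions.
* **Somatomotor exclusion.**  Parcels whose atlas network label is
  somatomotor *and* whose cohort-mean SUVR falls in the lowest decile are
  excluded from epicentre selection (a mask file overrides).  Excluded
  parcels carry a `-inf` score and can never be selected, but they remain
  in the spreading regression, which therefore uses 200 − 10 = 190 regions
  at defaults.

Scores are `p_abn(SUVR) × SUVR`; each participant's epicentres are the
top-k (k = 10) scores, ties broken toward the lower parcel index for
reproducibility.  Group-level epicentres are the top-k parcels by
cohort-mean score.

## Connectivity template and spreading statistic

Frames with framewise displacement above 0.5 mm (configurable) are
censored; subjects with a censored fraction ≥ 0.30 are dropped from the
template.  Pearson correlations on retained frames are capped at
|r| ≤ 1 − 1e-7 before the Fisher transform so z stays finite; constant
parcels yield missing correlations.  Retained subjects' z-matrices are
averaged element-wise; the strongest `round(density × n_pairs)` edges are
kept (round-half-away-from-zero, ties broken by lower parcel indices, so
30% density is bit-reproducible: 5970 of 19 900 edges at 200 parcels).
Distance on retained edges is `1 − minmax(z)` — bounded, order-reversing
and deterministic; non-retained edges get distance 1 and self-distance is
0.  An inverse-z variant and min/median aggregation over epicentres exist
behind configuration switches but are off by default; the mean over the k
epicentres is the default region-to-epicentre-set distance.

The spreading statistic z-scores regional rates and distances across
non-epicentre regions and reports the standardized OLS coefficient, which
equals the Pearson correlation (the identity is asserted to 1e-12 in the
tests), with a classical two-sided p-value.  Degenerate variance yields a
flagged missing β rather than an exception.

## Association models

sTREM2 passes a normality gate first: a one-sample Kolmogorov–Smirnov test
against a normal with the sample moments; p < 0.05 triggers a natural-log
transform (the lognormal sTREM2 distribution makes this the expected
branch).  Standardization happens after the transform.  Region-wise models
z-score the outcome and continuous predictors per parcel (sex stays binary
and unstandardized) and report standardized coefficients with classical
p-values; the BH-FDR family is the 200 parcels within one model spec and
one predictor — the narrowest defensible family, since no canonical one
exists.  Rank-deficient designs flag the region and drop it from the
family.  The four predictor sets are: regional amyloid; sTREM2; both; both
plus baseline regional tau — always with age and sex.

The sTREM2–β association regresses the individual spreading β (z-scored) on
standardized log-sTREM2 with age, sex and global amyloid as covariates,
optionally adding global baseline tau or CSF p-tau.  Variance inflation
factors (`1/(1−R²)`, warning bound 5) check amyloid/sTREM2 redundancy.
The power gate uses the Fisher-z approximation
`power = Φ(√(n−3)·atanh(ρ) − z_{1−α/2})`; at ρ = 0.3 and α = 0.05 the
smallest certified n for 80% power is 85, and at ρ = 0 the one-tailed
approximation leaves α/2 — both documented behaviours, not bugs.

## Mediation

Three nested OLS fits (`M ~ X + C`, `Y ~ X + M + C`, `Y ~ X + C`) give
a, b/c′ and c; ACME = a·b, ADE = c′, proportion mediated = ACME/c (reported
missing when |c| < 1e-12 rather than exploded), and the reported difference
statistic is c′ − c (direct minus total).  For linear OLS, c − c′ = a·b
holds exactly on every dataset and is asserted to 1e-10.  Inference is a
nonparametric case-resampling percentile bootstrap (default 1000 draws,
seeded); two-sided p-values double the smaller tail fraction crossing zero.
Case resampling (not residual resampling) was chosen as the simplest fully
reproducible scheme.  X, M and Y are z-scored by default so paths are
standardized coefficients.

## The synthetic cohort

The generator emulates an ADNI-like non-demented sample; its defaults are
the study conditions:

* Strata (CU/MCI × amyloid-negative/positive) of 47/27/60/44 participants;
  age 69.7 ± 5.7 vs 72.4 ± 6.2 years, education, APOE ε4 and sex
  frequencies per amyloid group.
* sTREM2 lognormal, moment-matched to 3697.6 ± 2039.5 (negative) and
  3916.9 ± 2301.3 pg/ml (positive).
* 2–4 tau-PET visits over 3.0 ± 1.6 (negative) or 2.3 ± 1.2 (positive)
  years, jittered around an even schedule to avoid artificial balance.
* Amyloid-PET: tracer assigned at random with its own positivity cut-off
  (1.11 florbetapir, 1.08 florbetaben); regional SUVR = global + smooth
  per-network deviation + noise; Centiloid is a configurable linear map of
  the global SUVR (the calibration constants are site-specific, so generic
  defaults are used).
* Connectivity: a low-rank block (network) factor model; parcel loadings
  are jittered so edge strengths are distinct (heterogeneity 0 reduces to
  exact equal within/between-block correlations for tests).  The distance
  the generator plants is computed *by the connectome module itself* from
  this correlation structure, so the spreading signal lives in exactly the
  metric the analysis measures and recovery tests are well-posed.
* Accumulation: each amyloid-positive subject gets k = 10 epicentres drawn
  mostly (weight 0.8) from 30 "vulnerable" non-somatomotor parcels;
  regional rate = `(0.05 − 0.04·d̄)·(1 − γ·z)` SUVR/year with γ = 0.3 and
  z the standardized log-sTREM2 (theoretical moments, so the null γ = 0 is
  exact).  The multiplier is not clipped: positivity is required only in
  expectation, and clipping would bias the null.  Amyloid-negative
  subjects get a weak separate structure (0.010 − 0.010·d̄) with no sTREM2
  effect, reflecting that their dynamics are not otherwise specified.
* Baseline tau follows the two-signal model the mixture analysis assumes:
  non-specific N(1.10, 0.10) everywhere; in amyloid-positive subjects a
  region is *already abnormal* at baseline with probability proportional
  to 8 years of pre-baseline accumulation (capped at 0.9), epicentres
  always abnormal; abnormal draws come from N(1.90, 0.25) shifted down by
  up to 0.4 of the component gap for late-converting regions, so
  epicentres remain the hottest regions.  Abnormality is binary per
  region — a graded continuum instead would make regional distributions
  unimodal-skewed and defeat any two-component decomposition.
* MMSE declines linearly at `−20 × (global true tau rate)` points/year
  plus noise, floored at 0 and capped at 30.
* Template subjects' time series are multivariate draws from the planted
  correlation; motion spikes (FD floored at 0.55 mm, above the default
  scrubbing threshold) are inserted at a configurable frame fraction.

Ground truth (epicentre sets, true slope matrix, γ, mediation
coefficients, the planted correlation/distance, network labels) is recorded
for every cohort.

What the generator does **not** emulate: voxel-level imaging, partial
volume effects, practice effects on MMSE, APOE-driven disease mechanisms,
non-linear trajectories, or real spatial autocorrelation of cortical maps.
Passing recovery tests therefore shows the pipeline correctly estimates
the structures it assumes — not that those assumptions hold in any real
cohort.

## Problem sizes in tests and the acceptance script

The acceptance script runs the full default cohort (178 participants, 200
parcels, 69 template subjects, mixed-effects slopes, 1000 bootstrap
draws).  Calibration tests use 500 replicates of reduced problems chosen as
the smallest sizes at which the targeted behaviour is identifiable: 60
amyloid-positive subjects × 60 parcels with least-squares slopes for the
γ = 0 null, and n = 100 with 199 bootstrap draws for the a = 0 mediation
null; both use a 0.05 ± 0.035 acceptance band (~3.6 binomial standard
errors at 500 replicates), fixed in advance.  Planted-direction recovery
tests use the low-noise condition (tau measurement noise 0.01 SUVR, slope
jitter 0.001 SUVR/year) under which sign identification is reliable.

## Known limitations

* The somatomotor exclusion criterion (network label + lowest-decile mean
  SUVR) is one operationalization of an under-specified rule; real
  analyses should supply an explicit mask file.
* The BIC unimodality guard can zero out regions with a genuinely tiny
  abnormal fraction (< ~5% of participants) at cohort sizes this small.
* Mediation inference is associational: no sensitivity analysis for
  sequential ignorability is provided.
* Empirical-Bayes shrinkage at 2–4 visits attenuates between-participant
  slope differences; individual-level associations (e.g. sTREM2–β) are
  conservative under the mixed path relative to per-subject least squares.
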