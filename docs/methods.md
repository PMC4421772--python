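# Methods

`cytovar` implements a population-based in vitro hazard analysis: from raw
plate-format cytotoxicity screens of genotyped lymphoblastoid cell lines to
per-chemical EC10 distributions, technical-noise-corrected toxicodynamic
variability factors, comparison with in vivo variability, and genome-wide
association of the concentration–response profile.

## Concentration–response model and EC10

Raw luminescence is normalised per plate against control-well medians: the
negative (vehicle) controls define viability 1 and the positive (kill)
controls define 0,

    y = (signal − median(pos)) / (median(neg) − median(pos)).

Medians rather than means anchor the normalisation so a single aberrant
control well cannot move the scale.

Each 8-point profile is fitted with a logistic viability model,

    y = η + ε,   ε ~ N(0, σ²),   logit(η / θ_max) = β0 + β1·d,

where `d` is log10 molar concentration, θ_min is fixed at 0 (so weakly
cytotoxic chemicals remain estimable) and θ_max, the zero-concentration
plateau, is estimated because plates drift from the nominal value of 1.
All "log concentration" quantities are log10 molar; decade-wide ranges read
naturally in base 10.

With Gaussian errors and σ² profiled in closed form, the maximum-likelihood
estimate of (β0, β1, θ_max) is the nonlinear least-squares solution; the
fit uses multi-start Levenberg–Marquardt (5 candidate midpoints × 2 slope
scales, convergence tolerance 1e-12 on the scaled step and cost). The
profiled σ² is floored at 1e-12 viability² so the log-likelihood stays
finite on noiseless synthetic profiles; the floor is far below any real
assay noise and never binds on data.

**EC10.** The point of departure is the concentration producing a 10%
viability decrement from the *fitted* plateau, η = 0.9·θ_max, giving
`log10 EC10 = (ln 9 − β0)/β1` for β1 < 0. Profiles with β1 ≥ 0 or a
solution above the highest tested concentration (92 μM) are censored there
and reported as "no-effect"; censored values are excluded from variability
summaries (their count is reported) and from batch-mean estimation.

**Low-toxicity exception.** When the response at the highest concentration
exceeds 0.4, θ_max is fixed rather than estimated. The default fixes it at
the zero-concentration plateau estimate (mean of the two lowest-
concentration responses); an alternative reading — fixing at the observed
top-concentration response — is available behind a switch
(`theta_max_rule="top"`). The default was chosen because the plateau of a
monotone-decreasing viability curve sits at *minimum*, not maximum,
concentration.

**Outlier rule.** Each point is dropped in succession and the model
refitted; a point is flagged iff the maximised likelihood of the reduced
fit exceeds 10× the full-fit likelihood (Δ log-likelihood ≥ ln 10). One
pass only: all flags are collected against the full fit, then a single
refit on the non-flagged points supplies the final parameters. If flagging
would leave fewer than 4 points, the least-offending flags are rescinded
and a warning logged. Measured operating characteristics at 5% well noise
(see `analysis/05_method_properties.py` and the acceptance harness): the
per-well false-flag rate is ~2.5% and sensitivity to a 0.5-viability-unit
displacement is ~90%. Because eight wells are tested per profile, roughly
one clean profile in five carries at least one (harmless) false flag —
an intrinsic property of the factor-10 rule at this noise level, not an
implementation artefact; flags agree exactly with a brute-force drop-one
oracle.

**Batch correction and aggregation.** Per chemical, an additive batch
effect (batch mean of non-censored log EC10 minus grand mean) is subtracted
from each plate-level value; corrected values are averaged across replicate
plates per line. The method is deliberately the simplest invertible one —
the correction's only downstream consumer is a mean/variance summary.
Replicate counts n′ and pre-average values are retained for the
sampling-variance stage.

## Variability factors and shrinkage

Per chemical, empirical quantiles (linear interpolation of order
statistics) of per-line log10 EC10 give the toxicodynamic variability
factor `TDVF = 10^(q50 − q01)` — the fold-ratio between the median
individual and the 1% most sensitive individual, the quantity the default
10^(1/2) toxicodynamic uncertainty factor stands in for. Below 100 usable
lines a warning is logged: the 1st percentile is unreliable in small
panels.

Observed between-line variance is inflated by technical noise. The
per-observation sampling variance σ_s² is estimated conservatively from
cross-batch replicate pairs (two-observation sample variance, averaged
across pairs), and

    VIF = var(logEC10) / (var(logEC10) − σ_s²/mean(n′)),
    shrunken TDVF = 10^((q50 − q01)/√VIF),

with var(logEC10) the across-line sample variance of the batch-corrected,
replicate-averaged values. When σ_s²/mean(n′) ≥ var(logEC10) the VIF is
undefined and no shrunken factor is reported — the "technical variability
too large" condition. A defined VIF is ≥ 1 by construction; VIF < 1 is
rejected as a data error.

In vivo toxicodynamic variability reported as a log-normal geometric SD is
converted to the same scale via `GSD^z99`, z99 = Φ⁻¹(0.99) ≈ 2.326 (the
median-to-1%-tail ratio of a log-normal). The in vitro and in vivo factor
distributions are compared by a two-sample Kolmogorov–Smirnov test on
log10(factor) with the asymptotic p-value (sample sizes in the hundreds
and dozens justify it); reported "90% intervals" are central empirical
5th–95th percentile ranges, not bootstrap CIs of the median (a bootstrap
option exists in `compare_distributions` consumers but the central range
is the default reading).

## Association

**Marker QC.** SNPs are dropped for call rate < 95%, MAF < 0.01 or a 1-df
chi-square Hardy–Weinberg p < 1e-6 (hard calls; dosages rounded for
counting). The multivariate test additionally requires ≥ 20 samples in
each genotype class (its p-values rely on asymptotic theory).

**Covariates.** Intercept, sex, laboratory-batch indicators and the first
10 principal components of the column-standardised dosage matrix
(constant SNPs dropped, missing dosages mean-imputed; component signs fixed
by the largest-magnitude loading).

**Multivariate route.** For genotype class i and individual j,

    Y_ij = X_ij β + μ_i + e_ij,   e_ij ~ N(0, Σ),

with Y the 8-concentration response vector (replicate plates averaged per
concentration, matching the EC10 treatment of replicates) and Σ
unstructured. The 2-df genotype effect is tested by Pillai's trace
V = Σ λ/(1+λ) over the eigenvalues of E⁻¹H (H, E the hypothesis and error
SSCP matrices), with the standard F approximation
F = [(2n+s+1)/(2m+s+1)]·V/(s−V), s = min(p, q), m = (|p−q|−1)/2,
n = (v_e−p−1)/2. The implementation is validated against an independent
projection-matrix/eigenvalue oracle (1e-8) and collapses exactly to the
ANCOVA F-test for a single response. The reported effect size is
`partial R² = V/s` — bounded in [0, 1], reducing to the univariate partial
R² at p = 1; this is a documented convention, since "explained variance"
has no unique multivariate definition.

**EC10 route.** OLS of log EC10 (optionally rank-based inverse-normal
transformed, Φ⁻¹((r−0.5)/n)) on additive allele dosage plus covariates,
Wald p for the dosage term. The dense-variant scan is two-stage: an
untransformed prefilter at p < 5e-8, then recomputation of survivors on
the transformed scale — phenotype outliers that manufacture raw-scale hits
are defused by the transform.

**FDR and reporting.** q-values are computed within (chemical, method)
families: Benjamini–Hochberg by default, or Storey with fixed λ = 0.5
(π̂0 = #{p > λ}/((1−λ)m), capped at 1). Significant results are pruned
greedily by ascending p within ±1 Mb on the same chromosome. For a single
SNP across the chemical panel, the same fixed-λ π̂0 estimates the
proportion of chemicals with a real association (1 − π̂0, and the rounded
expected count).

**Heritability concordance.** The package does not estimate heritability
(external variance-component tools do); it implements the surrounding
concordance simulation: treating one estimator's per-chemical estimates as
truth, add independent N(0, SE²) errors per arm, and record the Spearman
correlation over 10,000 replicates — the rank agreement two noisy unbiased
estimators *should* show.

## Synthetic data generator

The generator emulates the structure the analysis assumes, with defaults
matching the emulated screen: 1,086 lines from 9 equal-sized populations,
179 chemicals, 8 log-spaced concentrations from 0.33 nM to 92 μM, 1–2
plates per line (a second plate with probability 0.65, in a batch drawn at
random, so replicates fall within or between batches).

- **Genotypes:** Balding–Nichols — ancestral frequency uniform on
  `maf_range` (default 0.05–0.5), per-population frequencies
  Beta(p(1−F)/F, (1−p)(1−F)/F) at F = FST (default 0.10, a typical
  continental-scale divergence), genotypes binomial(2, p_pop). SNPs are
  independent (no LD) — sufficient for testing single-marker machinery,
  not for LD-aware methods. An optional trio mode emits parent–parent–
  child triples by Mendelian transmission.
- **True potencies:** baseline(chemical) + population shift
  (SD 0.10 decades) + additive causal effects × allele count + per-line
  N(0, 0.3²) scatter. The 0.3-decade line SD reproduces the observed
  scale of between-line variation (raw TDVF near 10^(2.326×0.3) ≈ 5).
  High-concentration-only causal effects are deferred to plate generation:
  they shift viability at the top concentration only (per-allele, in
  viability units) and leave the true EC10 untouched — the pattern that
  motivates the multivariate test.
- **Plates:** per profile the slope β1 is drawn uniform over Hill
  coefficients 1–3 (β1 ∈ [−3 ln10, −ln10] per log10-molar unit), the
  steepness range typical of single-target cytotoxicity curves — the
  emulated screen reports no slope distribution, so this is the package's
  one free distributional choice. Plate plateaus drift uniformly in
  [0.85, 1.05]; batch shifts are N(0, 0.1²) decades; wells get additive
  N(0, 0.05²) viability noise; outlier wells (rate 1%) are displaced by
  ±0.5 viability units with random sign. Signals are mapped to a raw
  luminescence scale by a per-plate affine transform anchoring the control
  medians at 40,000 (vehicle) and 2,000 (kill) with 5% multiplicative well
  noise — arbitrary but fixed, since raw luminescence scales carry no
  information after normalisation.
- **Ledger:** every injected outlier well, causal assignment, batch shift
  and plate plateau is recorded for scoring.

What the generator does *not* emulate: linkage disequilibrium, imputation
dosage uncertainty, growth-rate confounding, spatial plate effects, or
non-Gaussian assay noise. Passing tests therefore demonstrate correctness
of the estimators under the stated model, not robustness to every artefact
of real screens.

## Problem sizes and numerical choices

The checked-in studies run at sizes chosen to make their Monte-Carlo error
small relative to the property being asserted: 200 profiles for EC10
recovery, 1,000 + 1,000 profiles for the outlier rule, 100 chemicals × 500
lines for shrinkage recovery, 5,000 null SNPs (n = 500 lines) for
calibration, 500 simulations (n = 100 lines, genotype composition fixed at
25/50/25 to honour the ≥ 20-per-class floor) for the power comparison, and
20 replicate 179-chemical panels for the π0 mixture (a single panel leaves
~0.07 Monte-Carlo noise on the recovered proportion). The analysis drivers
under `analysis/` use a 150-line × 8-chemical screen.

Degenerate inputs are handled explicitly: plates without both control
classes are rejected with a logged reason; fits with < 4 usable points are
refused; chemicals in a single batch pass through correction unchanged;
chemicals without cross-batch pairs get no shrunken factor; single-class
genotypes and rank-deficient designs refuse the test rather than return
garbage.

## Known limitations

- The EC10 sits on the curve's shoulder; at 5% well noise its median
  absolute error is ≈ 0.1 decades and, for very steep curves, the
  8-point-per-6-decades grid localises the transition only to the
  inter-point spacing.
- The factor-10 outlier rule is a likelihood heuristic, not a calibrated
  test; its false-flag rate varies with noise level.
- Batch correction assumes additive, chemical-specific batch effects.
- The asymptotic KS p-value is slightly conservative at the in vivo
  sample size (n = 34).
- No kinship mixed model: the association stage assumes the unrelated
  subset.
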