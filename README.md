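# cytovar

Population-scale *in vitro* hazard analysis for chemical risk assessment:
from raw plate-format cytotoxicity screens of genotyped human cell lines to
per-chemical EC10 distributions, toxicodynamic variability factors, and
genome-wide association of the concentration–response profile.

Risk assessments classically cover human toxicodynamic variability with a
generic 10^½ (~3.16-fold) uncertainty factor. Screening a large panel of
genotyped lymphoblastoid cell lines against a chemical library over a full
concentration series makes that factor measurable chemical by chemical —
and makes the genetic architecture of susceptibility mappable. This
package implements that analysis end to end, with a synthetic-data
generator carrying a complete ground-truth ledger so every estimator can
be scored against known truth.

## The models

**Concentration–response.** Normalised viability `y` at log10 molar
concentration `d` follows

    y = η + ε,  ε ~ N(0, σ²),  logit(η/θ_max) = β₀ + β₁·d,  θ_min = 0,

fitted per (chemical, line, plate) by maximum likelihood with automatic
drop-one outlier rejection (a point is flagged when removing it improves
the maximised likelihood ≥ 10-fold). The point of departure is the EC10,
the concentration giving a 10% decrement from the fitted plateau:
`log₁₀ EC10 = (ln 9 − β₀)/β₁`; curves that never drop 10% within the
tested range (0.33 nM–92 μM) are censored as "no-effect". Plate-level
values are batch-corrected and averaged across replicates per line.

**Variability.** Per chemical, `TDVF = 10^(q50 − q01)` — the fold-ratio
between the median and the 1%-most-sensitive line. Technical noise
estimated from cross-batch replicate pairs gives a variance inflation
factor `VIF = var/(var − σ̂s²/mean(n′))` and a shrunken factor
`10^((q50−q01)/√VIF)`. In vivo variability reported as a log-normal
geometric SD converts to the same scale as `GSD^2.326` (the 99% normal
quantile), enabling a Kolmogorov–Smirnov comparison of in vitro and
in vivo factor distributions.

**Association.** Two routes per (chemical, SNP): a multivariate ANCOVA of
the full 8-concentration profile, `Y = Xβ + μ_genotype + e, e ~ N(0, Σ)`,
tested by Pillai's trace (sensitive to effects confined to the highest
concentrations, which leave the EC10 unchanged), and an OLS regression of
log EC10 on additive dosage with an inverse-normal-transform two-stage
variant for dense scans. Marker QC (call rate ≥ 95%, MAF ≥ 0.01, HWE
p ≥ 1e-6, ≥ 20 per genotype class for the multivariate test), sex, batch
and 10 genotype PCs as covariates, per-chemical FDR (q < 0.10), ±1 Mb
regional pruning, and a fixed-λ π₀ estimate of one SNP's true-discovery
proportion across the chemical panel.

See `docs/methods.md` for assumptions, parameter defaults and limitations.

## Worked example

The numbered drivers under `analysis/` run a complete scaled study — 150
lines from 3 populations, 8 chemicals, 2,000 SNPs, 1–2 plates per line,
with one additive causal SNP (0.25 decades/allele on chem000) and one
high-concentration-only causal SNP (chem001) injected:

```
$ python analysis/01_simulate.py
simulated 150 lines x 8 chemicals on 247 plates (23,712 wells)
injected 176 outlier wells (1.11% of treatment wells)

$ python analysis/02_fit_ec10.py
fitted 1976 plate-level profiles -> 1200 (chemical, line) EC10 values (2 censored/no-effect)
recovery: median |log10 EC10 error| = 0.136 decades (90th pct 0.414)
outlier wells: 176 injected, 650 flagged, recall 0.84, precision 0.23
replicate log EC10 correlation over 772 pairs: r = 0.835

$ python analysis/03_variability.py
8 chemicals summarised; 4 with a shrunken factor (no cross-batch pairs or excess technical noise otherwise)
raw TDVF: median 7.08 (range 4.96-9.81); shrunken median 3.48
in vitro vs (synthetic) in vivo factors: medians 3.48 vs 2.96, KS D = 0.279, p = 0.832
population ANOVA: 0 of 8 chemicals with q < 0.05

$ python analysis/04_association.py
marker QC: 1994 of 2000 SNPs pass; 1027 eligible for the multivariate test (>=20 per genotype class)
3 associations at per-chemical q < 0.1; 3 after +/-1 Mb regional pruning:
  chem001 x snp000380 [magwas] p = 3.10e-22, q = 0.000, partial R2 0.399
  chem000 x snp000196 [ec10_lm] p = 1.09e-06, q = 0.002
  chem003 x snp001778 [magwas] p = 9.29e-05, q = 0.095, partial R2 0.152
```

Reading the output: the fitted EC10s track truth to ~0.14 decades under
realistic plate noise; the raw median TDVF of 7.1 shrinks to 3.5 once
technical variance is removed (the generator's true between-line scatter
of 0.3 decades corresponds to a factor of 5.0; an 8-chemical panel leaves
the medians noisy); and the high-concentration-only SNP — invisible to
any EC10 summary — is the study's strongest multivariate hit
(p ≈ 3 × 10⁻²², partial R² 0.40), while the additive SNP surfaces in the
EC10 regression. The liberal outlier precision (0.23) is intrinsic to the
factor-10 likelihood rule at 5% well noise: ~2.5% of clean wells are
flagged, which costs little since refits average over the remaining seven
points.

`analysis/05_method_properties.py` measures the estimators' operating
characteristics (recovery error, false-flag rate and sensitivity,
shrinkage recovery, null calibration, multivariate-vs-EC10 power, π₀
mixture recovery) at reduced size; `cytovar.studies` holds the full-size
versions.

A configurable pipeline over the same stages is available as a CLI:

```
cytovar all --config config.yaml --seed 7 --outdir run/
```

with subcommands `simulate | fit | variability | gwas | validate`, a YAML
config whose thresholds default to the analysis's standard values, and a
manifest (config hash, per-stage row counts) making runs byte-for-byte
reproducible at fixed seed.

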