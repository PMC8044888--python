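# Methods

## Scientific setting

The package implements a one-sample Mendelian-randomization (MR) analysis of
type 2 diabetes mellitus (T2DM) and late-life cognitive status, plus the
surrounding pipeline: polygenic-score (PGS) construction from external GWAS
weights, Langa-Weir classification of a cognition summary score,
epidemiological sample selection, multivariable logistic models under
nested adjustment sets, instrument diagnostics, and two-sample MR
estimators. Because the motivating cohort's individual-level data are
access-restricted, a synthetic-data generator reproduces the *statistical
structure* the analysis assumes; every stage is tested against that
generator and against worked examples that are fully computable from
published tables.

## Polygenic scores

`PGS_i = Σ_j W_j G_ij` over the variants shared by the weight table and the
genotype matrix. Harmonization aligns each weight to the genotype's counted
allele: identical alleles keep the weight, swapped alleles negate it
(algebraically identical to scoring the complementary dosage `2 − G` up to a
constant), and otherwise the strand complement is tried. Strand-ambiguous
(A/T, C/G) variants are kept by default — the source scoring pipeline scores
all overlapping SNPs and applies no palindrome filter — with a `drop` policy
switch; irreconcilable variants are dropped and counted, never silently
kept. P-value thresholding retains variants with `p ≤ cutoff` (the default
cutoff 1 keeps everything; the sweep {1, 0.3, 0.1, 0.05, 0.01, 0.001} is
exposed in the pipeline). Region masks use inclusive 1-based bounds, the
natural reading of printed interval endpoints. Standardization is z-scoring
with the n−1 denominator within ancestry groups, applied once on the full
analysis sample before subsetting; missing dosages are not modelled (the
generator emits complete genotype data, and a real-data pathway would need
an explicit missingness policy — documented as unsupported).

## Cognitive status and selection

Self-respondents are classified on the 27-point scale (normal 12–27, CIND
7–11, dementia 0–6), proxy respondents on the 11-point scale (normal 0–2,
CIND 3–5, dementia 6–11); out-of-range scores raise. Selection keeps ages
50–90 inclusive ("younger than 50 or over 90" excludes strictly outside the
closed interval) and removes participants with a prior-wave dementia record
who present as cognitively normal in the current wave; rules are applied in
that order with per-rule tallies so selection flows are auditable. Analyses
run in two subsets — CIND vs. normal and dementia vs. normal — with normals
appearing in both; a subset with a single outcome class is flagged unusable.
Missing-data handling is complete-case within each model's variable set, so
each fitted model records its own n.

## Estimation

Logistic models are maximum-likelihood fits (Newton, tolerance 1e-8, 50
iterations, observed-information SEs) via statsmodels; separation and
non-convergence are surfaced as flags, and rank deficiency raises with the
collinear columns named. Confidence intervals are `β ± 1.96·se` everywhere
(no profile likelihood), matching the arithmetic of printed tables.
Adjustment sets: crude (none); primary (age, sex, years of education,
APOE-ε4, five ancestry PCs); health status (primary + stroke, hypertension,
BMI, smoking coded ordered 0/1/2 never/former/current, drinking); AD
genetics (health status + AD polygenic score). No multiple-testing
correction is applied anywhere; nominal p < 0.05 is the reporting
convention.

The one-sample causal estimate is the Wald-type ratio `β_ZY/β_ZX` with the
two-term (first-order) Delta-method variance; the first-order form is used
because it reproduces the printed worked example (OR 1.04, CI 0.90–1.21) at
two decimals. Both regressions inside `OneSampleMR` are restricted to the
identical complete-case rows before fitting — a ratio of estimates from
different samples would not be a one-sample Wald ratio. Relevance is the
improvement χ² (2·Δlog-likelihood for adding the instrument); values ≤ 10
flag weakness, and a separate Delta-guard warns when `|β_ZX| < 10·se_ZX`.
Weak-instrument results are flagged but still reported. The observational
and MR estimates are compared with the Altman–Bland interaction test
`z = (β_a − β_b)/√(se_a² + se_b²)`.

Two-sample estimators operate on summary statistics harmonized to the
exposure effect allele (sign flips on swaps, strand complements tried, no
LD clumping): fixed-effect IVW (pooled `Σw_j r_j/Σw_j`, `w_j =
β_exp_j²/se_out_j²`; a multiplicative random-effect switch inflates the SE
when heterogeneity exceeds its expectation), MR-Egger as WLS with a free
intercept and residual dispersion floored at 1 (the directional-pleiotropy
test), and the weighted median (inverse-variance-weighted 50th percentile
with linear interpolation, SE from 1,000 seeded parametric-bootstrap
draws — the source analyses delegate to established tooling without stating
internals, so the bootstrap size is this package's choice).

Population attributable fractions implement both Levin
(`p(OR−1)/(1+p(OR−1))`) and Miettinen (`p_cases(OR−1)/OR`); with OR 1.30
they give 5.4% and 5.8% respectively, and neither reproduces the 4.4%
printed in the motivating analysis, whose formula is unstated — so no test
asserts that figure.

## The synthetic generator

The generator is a pure function of `(params, seed)` (per-stage
`SeedSequence` children keep individual generators reproducible in
isolation). Defaults define the emulated study conditions and were fixed
from the published descriptive table:

| parameter | default | meaning |
|---|---|---|
| n_individuals | 8,000 | analysis-sample scale |
| n_variants / n_causal | 200 / half | instrument panel (no LD; variants independent) |
| maf_range | (0.05, 0.5) | uniform allele frequencies, HWE dosages Binomial(2, f) |
| alpha0 | −1.5 | exposure intercept → ≈19% T2DM prevalence |
| alpha_pgs | log 1.66 | exposure log-OR per SD of *true* score |
| gwas_noise_sd / true_effect_sd | 0.02 / 0.08 | weight noise; published score correlates ≈0.94 with truth, observed first-stage OR ≈ 1.6 |
| theta | 0 | causal log-OR of outcome per unit binary exposure (null default) |
| delta_pleio | 0 | direct score→outcome path (exclusion-restriction violation dial) |
| alpha_ad | 0 | AD-score→cognition path, used to construct reverse-MR instruments |
| proxy_rate | 0.05 | proxy respondents (no published value; a stand-in) |

Covariate marginals: age truncated N(70, 10²) on [50, 90]; 58% female;
education N(13.3, 2.5) rounded; APOE-ε4 26.5%; five standard-normal PCs;
health covariates with realistic marginals but independent of the score, so
the confounder screen is null-calibrated. Age, sex, education and APOE-ε4
act on both exposure and outcome (true confounding, sized so the crude
exposure–outcome OR exceeds the adjusted one) but never on the genotype,
preserving the MR independence assumption unless `delta_pleio ≠ 0`. GWAS
p-values come from the simulated Wald statistic `weight/gwas_noise_sd`, so
threshold sweeps behave like real summary statistics.

The cognition outcome is a latent index `−(θ·t2dm + δ·score + α_AD·ad +
confounders) + Logistic(0,1)` mapped through a fixed monotone
piecewise-linear transform to the 0–27 integer scale (0–11, reverse
oriented, for proxies) with cut points −2.0 (CIND) and −3.8 (dementia),
chosen to give ≈17% impairment and ≈3.5% dementia. Only the classified
status matters downstream, so any monotone mapping populating all three
classes is equivalent. Two-sample summary statistics come from two disjoint
simulated samples with a *continuous* exposure, so the IVW estimand is
exactly `theta` there.

What the generator does **not** emulate: linkage disequilibrium, imputation
dosages, family structure, missing data, survey weights, and real ancestry
structure (PCs are pure noise covariates). Passing simulation tests
therefore demonstrate the estimators' statistical behaviour under the
assumed model, not robustness to those real-data features.

## Ratio estimands for binary exposures

A point that matters for interpreting both the simulations and the
motivating analysis: with a *binary* exposure, the ratio of log-ORs
`ln(OR_ZY)/ln(OR_ZX)` does not estimate the exposure's conditional log-OR
θ. To first order the reduced form is `θ·(dE[X]/dZ) = θ·β_ZX·p(1−p)`
(p = exposure prevalence), so the ratio converges to approximately
`θ·p(1−p)` — at p ≈ 0.19 an attenuation factor of ≈ 0.15. The estimator is
exactly the one used in the emulated analysis and is interpreted, as there,
as the effect per unit increase in the log-odds (liability) of exposure;
the package reports it without "correcting" it. Two consequences are worth
noting. First, simulation coverage of a latent θ ≠ 0 by the ratio CI is
structurally poor (measured ≈13% at θ = log 1.3) even though the estimator
and its Delta SE are correct for their own estimand — under the global null
the type-I error is nominal, which the seeded simulations confirm. Second,
an observational OR of 1.30 with a first stage of 1.64 *implies* a reduced
form near 1.02 and a Wald ratio near 1.04 even if the observational
association were wholly causal, so the interaction test between the two
scales partly reflects this scale mismatch rather than confounding alone.

## Numerical and testing choices

Deterministic anchors are asserted at printed precision (2 d.p.); the
reconstruction of (OR, CI) from printed tables is exact only to printed
precision because published CIs are not exactly log-symmetric. Monte-Carlo
suite sizes are package choices balancing resolution against run time: the
acceptance-grade properties run 100 seeded replicates at n = 8,000
(type-I error, coverage, instrument strength); the logistic CI-coverage
invariant runs 60 replicates at n = 4,000; two-sample IVW coverage runs 50
replicates at n = 20,000 per sample with 50 instruments; the confounder
screen calibration runs 200 replicates of 5 screens at n = 1,000. Replicate
seeds derive from a fixed base. The weighted-median bootstrap and all
generators accept explicit seeds; the pipeline is byte-deterministic given
(config, seed).

## Known limitations

Ordinal (proportional-odds) outcome models are deliberately out of scope
(their assumption fails for this outcome in the emulated study, which fell
back to the two binary subsets, as this package does). LD-aware instrument
selection, clumping, Steiger filtering, MR-PRESSO and multivariable MR are
not implemented. The negative-control diagnostic conditions on observed
exposure status and is informative about direct score→outcome paths, not
about collider structures it could itself induce. African-ancestry
re-analysis is a configuration change (different inputs), not a distinct
code path.
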