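# Methods

This note documents the models behind `famprs`, the defaults of the
synthetic family-cohort generator, the numerical choices in the solvers, and
what the simulation-based tests do and do not establish about real data.

## Synthetic family cohorts

`simulate_cohort` generates nuclear families founder-first. Parental
genotypes at each of `n_snps` independent biallelic SNPs are drawn in
Hardy–Weinberg proportions at a MAF sampled uniformly from `maf_range`
(default 0.05–0.5, a common-variant spectrum typical of candidate panels);
offspring genotypes follow Mendelian transmission (each parent passes the
counted allele with probability g/2). Linkage disequilibrium between SNPs is
deliberately absent: independent markers suffice to exercise every
downstream stage, and the score construction does not prune by LD.

BMI is additive on the natural scale:

    BMI = mu + b_sex (male - 1/2) + b_age (age - mean age) + s + e

* `s` is the true polygenic score, `s = sum_j a_j g_j` centred; per-SNP
  effects `a_j` are Gaussian draws rescaled so that Var(s) equals
  `h2_score * bmi_base_sd^2` (default `h2_score = 0.075`, the share of BMI
  variance a candidate-panel score plausibly carries).
* `e` is Gaussian with variance chosen so the total unascertained BMI
  variance equals `bmi_base_sd^2` (default SD 6.5 kg/m²) after accounting
  for the sex, age and score terms. Heavy-tailed alternatives are not
  implemented; BMI in adults is mildly right-skewed, so Gaussian noise is an
  idealisation.
* Covariate defaults: `sex_effect = 0.5` kg/m² for males, `age_effect =
  0.05` kg/m² per year; parents' ages uniform on 35–60 y, offspring 15–35 y.
  Age and sex are independent of genotype — they enter only as adjustment
  covariates downstream, so correlating them with the score would add
  nothing the tests could detect.
* Offspring count per family: `min + Binomial(max - min, p)` with `p`
  matching the configured mean (default (1, 6, 1.97), giving ≈4.0 members
  per family and ≈880 individuals from 222 families).

**Ascertainment.** Families qualify when at least one parent AND at least
one offspring reach the ascertainment threshold (default 32 kg/m²);
qualifying families are kept by rejection sampling of whole families, which
reproduces the rule exactly. The rule is applied to a *recruitment-time* BMI
equal to the measured BMI plus Gaussian drift (`recruitment_bmi_noise_sd`,
default 6 kg/m²). This drift is not cosmetic: with ~2 offspring per family a
literal reading of the rule guarantees two currently obese members in a
~4-person family, pinning the cohort obesity prevalence near 50%, whereas
real family studies recruited this way report ~28% — the years between
recruitment and measurement regress members toward the population mean. The
default intercept `bmi_base_mean = 22.0` was set with the prescribed
bisection calibration (`calibrate_base_mean`) so that post-ascertainment
obesity prevalence is ≈0.28 and the measured BMI SD ≈7, matching the target
study conditions. Setting the drift to 0 recovers the literal rule.

**Splitting.** The 80/20 discovery/validation split is individual-level by
default (partition sizes floor(0.8 n) and the remainder), stratified by
obesity with largest-remainder rounding so partition prevalences differ by
at most one count. Whether the original study kept families intact across
partitions is not stated; a family-level split is available behind
`by_family=True`, and kinship handles partially split families by treating
a missing parent as an unrelated founder.

**What the generator does not emulate.** LD, genotyping batch effects,
assortative mating, shared-environment ("common household") variance beyond
the additive kinship term, age-by-genotype interaction, and secular BMI
trends. Tests passing on these cohorts show the estimators are correct under
the additive, random-mating model they assume — not that the pipeline is
robust to those real-data complications.

## Genotype QC

Per-SNP filters use strict inequalities exactly as such pipelines print
them: pass requires MAF > 0.01, call rate > 0.95, HWE exact P > 2.6e-4, and
imputation r² > 0.3 where an r² is recorded (a boundary value fails).
`fail_reasons` lists every violated filter. MAF and HWE are computed on
pedigree founders by default, since transmitted allele copies are not
independent draws; an all-individuals mode exists for parity with naive
pipelines. The HWE test is the conditional exact test (standard two-sided
rule: sum the probabilities of all heterozygote counts no more probable than
the observed one, given the allele counts), computed by the stable two-term
recurrence and compared in tests against an independent log-gamma
enumeration; the mid-p variant is not used, and a chi-square option exists
behind a flag.

## Kinship and mixed models

Kinship uses the recursive tabular method with founders assumed non-inbred
and mutually unrelated; the random-effect covariance is σ²_g · 2Φ (the
additive relationship matrix). Matrices are dense — cohorts here are a few
thousand individuals at most — but all solvers exploit the block-diagonal
family structure (blocks from family ids, or connected components of the
matrix), grouping equal-sized blocks into stacked arrays so per-iteration
linear algebra is vectorised.

The **linear mixed model** (BMI outcome) is fitted by REML: each family
block of 2Φ is eigendecomposed once, the variance ratio λ = σ²_g/σ²_e is
profiled by bounded scalar minimisation of the restricted likelihood on
log-λ ∈ [−12, 8] (the λ = 0 boundary is checked explicitly), and σ²_e has a
closed form at each λ.

The **logistic mixed model** (obesity outcome) uses penalised
quasi-likelihood: iterate the working linearisation, re-estimate σ²_g by
REML on the working variates (residual covariance = inverse weight matrix;
bounded search on log σ² ∈ [−18, 4] with the zero boundary checked), solve
the mixed-model equations for fixed effects and BLUPs, and declare
convergence when the largest parameter change is below 1e-6 (cap 100
iterations). Working means are clipped to keep weights ≥ 1e-6. Separation is
flagged (warning, estimate still returned) when any |β| exceeds 20; an
outcome with a single class raises an error. Inference is Wald with normal
tails, matching common GWAS reporting; likelihood-ratio tests are not
provided because the PQL criterion is not a true likelihood. PQL is known to
bias fixed effects toward zero for binary traits when σ²_g is large; at the
moderate variance components of family data (σ²_g ≲ 1) the bias observed in
the recovery tests is ~5% of a log-OR of 0.3, inside their tolerance. With
identity relatedness and no variance component the fit coincides with
ordinary IRLS logistic regression to 1e-3, which the tests verify against an
independent implementation.

Missing genotypes are mean-imputed to 2·(counted-allele frequency) both in
the scan and in scoring, so a missing call contributes its expectation; this
keeps score values comparable across individuals with different missingness.
Monomorphic SNPs are skipped with a reason rather than fitted. No
multiple-testing correction is applied in the scan: the downstream score
deliberately uses all SNPs, and the α = 0.05 significant set is reported
only as a summary.

## Score construction and stratification metrics

Default weights multiply allele counts by the odds ratio itself; log-OR
weighting is a first-class alternative (`mode="logOR"`) because the
field-standard convention and the construction reproduced here genuinely
differ — under OR weights a null SNP still adds a constant 1·g shift, which
changes the score location but not ranks much; under log-OR a null SNP adds
nothing. Quintiles are rank-based with stable tie-breaking; group sizes are
⌈n/5⌉ or ⌊n/5⌋ with the larger groups lowest.

The trend test is the Wald test on the continuous score's coefficient
(per score unit by default; per SD via `per_sd=True`, with
OR_sd = OR_unit^SD). Quintile effects enter one model as four indicator
contrasts against Q1; a quintile with no cases or no controls is flagged
non-estimable rather than dropped.

AUC is the rank-based (Mann–Whitney) statistic with ties counted ½,
computed on population-level predicted probabilities (random effect at
zero) — conditioning predictions on BLUPs would let the family effect
absorb part of the discrimination being measured. Optimism correction is
Harrell's bootstrap: resample individuals (family-block resampling
available, the safer choice under family correlation), refit, and subtract
the mean of AUC(resample fit on resample) − AUC(resample fit on original);
resamples that lose an outcome class are redrawn. Model comparisons use the
paired per-resample corrected differences with a bias-corrected (no
acceleration) percentile 95% interval; "significant" means that interval
excludes zero. NRI is category-free (no risk categories are defined for
obesity); IDI is the change in mean risk separation. Their intervals are
percentile bootstrap over individuals and p-values are normal-theory on the
bootstrap SE.

Variance explained by the score is reported two ways: primarily as the drop
in total REML variance (σ²_g + σ²_e) when the score enters the fixed
effects, as a fraction of the total sample BMI variance — this is the
definition under which a true score carrying 7.5% of variance is recovered
to ±0.01 at n = 10,000 — and alongside it the squared partial correlation of
BMI and score given sex and age. The two differ when the kinship term
absorbs genetic variance differently between the nested fits.

## Polygenic score power

`analytic_power` follows the classical training/target framework: m
standardised markers, per-SNP weight error variance 1/n_train, binary traits
as liability thresholds at the *sample* prevalence (the cohorts are
ascertained; no population-prevalence correction is attempted because the
sampling design provides none), and observed-scale attenuation
c(K) = φ(t)/√(K(1−K)). The input `score_r2_train` is the variance the
estimated score explains on the quantitative/liability scale in the training
population — the quantity a linear mixed model on the training sample
reports. Inverting the error model gives the implied true marker variance
v_g from r² = v_g²c₁²/(v_gc₁² + m/n_train); the expected squared target
correlation is then ρ² = r²·c₂², the test has ncp = n_target·ρ²/(1−ρ²) on
one chi-square df, and power is the noncentral tail probability. `pi_null`
(default 0: every SNP carries effect) only redistributes the true variance
in the Monte-Carlo check — with no p-value selection of SNPs it cannot move
the expected correlation. Infeasible inputs (implied v_g ≥ 1) raise a
parameter error. `mc_power` simulates the full cycle — train, estimate
weights by marginal correlation, score an independent target, test at α —
under the same generative model with standardised Gaussian genotypes
(equivalent to allele counts at these sizes, since only correlations enter);
agreement with the closed form within ±0.03 over a 3×3 grid (training
n=500, 20 SNPs, target n ∈ {100, 200, 400}, r² ∈ {0.02, 0.05, 0.10},
2000 reps/cell) is part of the test suite. The closed form uses the
expected correlation; in steep high-power regions the spread of the realised
per-replicate correlation makes simulated power fall slightly below it,
which is the dominant term in that ±0.03.

## Problem sizes in the test suite

Simulation-backed checks run at deliberately chosen desk scales: 10,000
individuals for variance-fraction recovery, 500 replicate family cohorts
(~250 individuals each) for log-OR recovery and CI coverage, 2000 null
replicates for scan calibration, 2000 Monte-Carlo repetitions per power-grid
cell, 200,000 gene-dropping replicates for the kinship oracle, and every
Hardy–Weinberg table up to 200 genotypes for the exact-test oracle. These
sizes give Monte-Carlo error comfortably inside each test's tolerance while
keeping the full suite runnable on a laptop.

## Known limitations

* PQL inference degrades for binary traits with large variance components
  (σ²_g ≫ 1) and small families; no adaptive-quadrature or MCMC fallback is
  provided.
* The optimism bootstrap refits the mixed model per resample; at B = 1000 on
  cohorts of several hundred this is minutes, not seconds.
* Power calculations assume independent markers and no p-value thresholding
  when building the score; the `pi_null` sensitivity knob does not implement
  threshold-selection curves.
* The generator's ascertainment-drift device reproduces realistic cohort
  prevalences but is one of several mechanisms (measurement error, secular
  trends, weight loss) that could; its SD is a modelling choice, not an
  estimate.
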