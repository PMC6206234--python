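# Methods

## Data model

A cohort is a panel of biallelic SNPs and a list of subjects with
case/control status, age (months), sex, tumor site of origin (cases
only) and unphased genotypes.  Genotypes are stored as variant-allele
dose 0/1/2; each SNP's common>variant orientation (e.g. rs110419 A>G)
fixes which allele is counted, making additive coding and
protective-genotype membership unambiguous.  The bundled study panel is
rs110419 A>G, rs4758051 G>A, rs10840002 A>G, rs204938 A>G and
rs2168101 G>T, in that order; for all five SNPs the variant-carrying
genotypes (dose ≥ 1) are the protective set.  Missing genotypes are
written `./.` in files and dropped per-analysis (complete-case); they
are never imputed.  The combined protective score is undefined for a
subject missing any panel genotype, so such subjects are excluded from
the combined analysis.

## Hardy–Weinberg QC

For control genotype counts (k₀, k₁, k₂) the variant-allele frequency
is q = (2k₂+k₁)/2N and expected counts are N(1−q)², 2Nq(1−q), Nq².
The test is the asymptotic 1-df Pearson χ² without continuity
correction, which reproduces the study's printed p-values to three
decimals.  An exact conditional test (`hwe_exact`) is available but not
the default.  Monomorphic loci return χ²=0, p=1 with a flag rather
than an error.  HWE is evaluated in controls by default, as is standard
for case-control QC.

## Odds ratios and logistic regression

2×2 contrasts use the cross-product OR with the Woolf log-scale SE and
a two-sided Wald p-value; 95% CIs use z = 1.959964 (the six-figure
normal quantile, needed to reproduce printed two-decimal CIs).  Any
zero cell makes the contrast inestimable (rendered "/") unless the
Haldane–Anscombe +0.5 correction is requested.  Two p-value conventions
are exposed side by side, matching the published tables: the Wald test
of ln OR for each OR column, and the Pearson χ² of the (collapsed)
genotype distribution for the separate distribution-P column.

The additive model is a maximum-likelihood logistic regression of
status on dose fitted to grouped counts; grouped (frequency-weighted)
and row-expanded data give identical estimates.  Fitting is delegated
to an IRLS GLM (statsmodels, binomial family); the module adds rank and
two-class checks, a complete-separation guard (|coef| > 15), and Wald
OR extraction.  Covariance is the inverse observed information.

Adjusted contrasts refit the model coding on individual records with
age as continuous months and sex as a male indicator (the age ≤18/>18
dichotomy is available through stratification instead; continuous age
is the default adjustment).  The het and hom contrasts drop subjects at
the non-contrasted dose, exactly as the crude 2×2 does.  Stratified
analysis runs one adjusted contrast per stratum; site strata compare
site-specific cases against **all** controls, since controls carry no
tumor site.  Degenerate strata yield inestimable rows, never a crash.
No multiple-testing correction is applied anywhere — the pipeline
follows the FPRP-based noteworthiness convention instead.

## FPRP

FPRP = α(1−π) / (α(1−π) + (1−β)π), with α the observed p-value at full
precision (not its display rounding — the published FPRP pair
0.009/0.027 for the rs110419 heterozygote row is reproducible only with
α = 0.0011), π the prior probability of a true association (default
grid 0.25, 0.1, 0.01, 0.001, 0.0001) and 1−β the power to detect a
hypothesized true OR₁ at level α.  SE(ln OR) is recovered from a
reported CI as (ln hi − ln lo)/(2·1.959964).  Power uses the two-sided
normal approximation Φ(−z_c−μ) + 1 − Φ(z_c−μ) with μ = ln(OR₁)/SE; the
default OR₁ is 0.67 for protective estimates and 1.5 for risk
estimates (reciprocal magnitudes), configurable.  Findings are
noteworthy below FPRP 0.2.  The source study's printed power column is
not reproducible from any standard power recipe at its printed inputs,
so `fprp_table` accepts an externally supplied power per row; the
internal power model is validated against Monte Carlo instead
(agreement within 0.003 at 10⁶ draws).

## Haplotype EM

Phase is unobserved: a genotype heterozygous at h loci is compatible
with max(1, 2^(h−1)) unordered haplotype pairs.  Under random mating
the EM iteration weights each compatible pair (h₁,h₂) by
θ_{h₁}θ_{h₂} (doubled when h₁≠h₂), normalizes within subject, and sets
each θ to its expected chromosome count over 2N.  The log-likelihood is
asserted non-decreasing at every iteration; convergence is a
log-likelihood gain below 1e-9 (default) within 1000 iterations.
Initialization is the product of single-locus allele frequencies
(deterministic); seeded Dirichlet restarts are optional, best
log-likelihood wins.  EM runs separately per group (cases; controls),
matching group-specific published counts; at a single locus the
estimate equals allele counting exactly.

Association contrasts each haplotype's expected chromosome counts
against a reference haplotype (default: the most frequent control
haplotype) in a 2×2 Woolf OR.  Estimability follows the displayed
integer counts: a haplotype whose expected count rounds (half-up) to
zero in either group is inestimable.  ORs are computed on unrounded
expected counts by default; a printed-counts mode takes rounded
integers as given to mirror published tables.  Haplotypes with
expected count below 0.5 in both groups are suppressed.  Optional
adjusted ORs expand each subject into chromosome rows weighted by
posterior haplotype dosages from a pooled EM and fit a logistic model
with age/sex covariates; with no covariates this reduces to the crude
expected-count 2×2.

A known limitation, visible in the null-coverage test: treating EM
*expected* counts as observed multinomial counts ignores
phase-uncertainty variance, so Wald CIs for heavily phase-ambiguous
haplotypes are mildly anti-conservative (per-haplotype null coverage
~0.88–0.97, ~0.92 aggregate, at the study's sample size).  This is the
convention of standard haplotype-association tools and of the source
analysis; a phase-uncertainty-aware variance is out of scope.

## Synthetic cohorts

Each simulated individual draws two haplotypes i.i.d. from a frequency
pool, so every locus is in HWE in the source population and LD is
induced solely by the joint haplotype frequencies (no recombination
model — the most that group-level haplotype tables can constrain).
Disease status is Bernoulli with
logit P(case) = β₀ + Σ_l effect(l, dose_l) + β_age·age + β_male·male,
and individuals accumulate by rejection until the exact case and
control quotas are met, mirroring case-control ascertainment.  A single
seeded generator drives the whole run, and the seed is recorded in
every output header.

Defaults are the study conditions: 313 cases / 762 controls; the
haplotype pool is the published control haplotype frequencies
(24 haplotypes, counts/1524); dominant protective effects of OR 0.6
(log-OR ln 0.6 at dose 1 and 2) at rs110419, rs4758051, rs10840002 and
rs2168101 and no effect at rs204938, the magnitudes of the published
dominant contrasts; β₀ = −2 (≈12% baseline risk, so study-sized cohorts
fill in a few thousand draws); age truncated-normal with the published
control moments (mean 33.04, SD 30.30, range 0.001–132 months);
P(male) = 0.5538; β_age = β_male = 0 unless confounding is being
studied.  Tumor sites are assigned to cases multinomially with the
published proportions (21.73 / 40.26 / 31.63 / 6.39%), independent of
genotype — the study reports no site-genetic structure, so none is
emulated.

What the generator does **not** emulate: population stratification or
admixture, genotyping error, missingness, relatedness, or any
site-of-origin genetic dependence.  Tests passing on these cohorts
therefore validate the estimators under clean ascertainment, not
robustness to those real-data complications.

## Numerical choices and problem sizes

- CIs use z = 1.959964; rounding for display is half-up to 2 decimals
  (ORs/CIs), p-values at 4 significant figures with "< 0.0001" below
  1e-4, "/" for inestimable cells; full precision is kept internally.
- Logistic fits: IRLS to tolerance 1e-10, max 100 iterations;
  non-convergence and separation raise informative errors.
- EM ties between restarts are broken by the first (deterministic)
  initialization; frequencies are reported for the full 2^L lexicographic
  haplotype space.
- Calibration studies use problem sizes chosen to keep the whole suite
  fast while leaving Monte-Carlo noise well below the asserted bounds:
  500 replicates of 2000+2000 for adjusted-estimator bias (< 0.03 on the
  log scale), 1000 replicates of 313+762 for type-I error
  (0.035–0.065 at α = 0.05), 60 replicates of 313+762 for haplotype CI
  coverage, 400 replicates of 762 controls for HWE p uniformity, and
  10⁶ draws per point for power validation.
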