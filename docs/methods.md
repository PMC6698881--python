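# Methods

## The design

A genome-wide polygenic score (GPS) predicts a trait among unrelated
individuals through a mixture of pathways: the direct effect of the alleles
an individual carries, but also family-level pathways — parents whose
genotypes shape the rearing environment (passive gene–environment
correlation, "genetic nurture"), shared environment correlated with parental
genotype, assortative mating, and population stratification. Dizygotic (DZ)
co-twins share all of these family-level pathways but differ in which
alleles they inherited, because meiotic segregation is random. Regressing
co-twin *differences* in outcome on co-twin *differences* in GPS therefore
isolates the direct effect; regressing family *means* on family means
absorbs everything else.

## The decomposition model

For twins i = 1, 2 in family j:

    Y_ij = α0 + βW (GPS_ij − GPS̄_j) + βB GPS̄_j + γ_j + ε_ij,
    γ_j ~ N(0, σγ²),  ε_ij ~ N(0, σε²)

with group-mean centering of the predictor so that βW (within) and βB
(between) are mutually adjusted. The intraclass correlation
ICC = σγ²/(σγ² + σε²) measures how much outcome variance is familial, and
the population-level total effect is the ICC-weighted mixture
βW (1 − ICC) + βB ICC, which always lies between the two coefficients.

**Estimation.** Restricted maximum likelihood (REML), the standard choice
for variance components; ML is available behind a flag and differs
negligibly at the sample sizes used here. Because every cluster has exactly
two members, rotating each pair onto its sum and difference contrasts makes
the covariance diagonal with two strata (relative variances 1 + 2λ and 1,
λ = σγ²/σε²), so the likelihood is profiled to a 1-D search over λ: a
coarse log-spaced grid on [0, 10⁶] followed by bounded Brent refinement,
with closed-form weighted least squares at each evaluation. λ = 0 (no
family variance) is a legal boundary solution and is flagged. Fixed-effect
standard errors come from the observed information at the optimum; Wald
p-values use the normal reference — bootstrap percentile intervals are the
primary inference.

A useful exactness property anchors the implementation: with no extra
covariates the two strata decouple and the REML fixed effects equal two
ordinary regressions — βW is the through-origin slope of co-twin outcome
differences on score differences, βB the slope of pair means on pair means.
The test suite verifies this identity to 10⁻⁶ against an independently
coded closed form, and checks the full covariate model against
`statsmodels.MixedLM`.

**Covariates** (e.g. family SES) enter as individual-level fixed effects
without further centering; a family-constant covariate automatically loads
only on the between part. Note that adjusting for an SES composite that is
itself partly *caused* by parental genotype is a conditioning choice, not a
causal identification: it is used here, as in the twin literature, to ask
how much of the between-family coefficient travels through measured SES.

## Bootstrap inference

Families (both twins together) are resampled with replacement to the
original pair count; the model is refit per replicate. Default 10,000
replicates; the validation suites use 500, which is ample for the SDs and
95% percentile endpoints used. The βW-vs-βB test divides the full-sample
coefficient difference by the SD of the replicate difference distribution,
referred to a standard normal — its type-I error is verified at ~5% by
simulation. The before/after-SES contrast of βB uses the *same* resamples
for both models (paired replicates); unpaired differencing would inflate
the difference SD. Attenuation, 100 (βB − βW)/βB, is reported with a
percentile CI and flagged undefined when |βB| < 10⁻⁸. Covariate-free
replicates use the exact closed form above (vectorized); covariate models
rerun the profiled REML per replicate on the same resample indices, so the
two paths are exchangeable and reproducible from one seed.

Benjamini–Hochberg FDR: the corrected threshold is the largest order
statistic p(k) with p(k) ≤ (k/m)·α; the `fit` command applies it across all
within/between coefficient p-values of a run as a single hypothesis family.

## Quantile twin-difference analysis

Signed co-twin differences (member 1 − member 2) are ranked by absolute GPS
difference into ten near-equal deciles (sizes differ by at most one; ties
break by stable input order). The lowest-vs-highest decile contrast uses
outcome differences oriented toward the higher-GPS twin — the orientation
makes the contrast directionally consistent with the signed through-origin
regression reported alongside; absolute differences are available as an
option. The through-origin regression of outcome differences on GPS
differences has no intercept because both variables negate under a twin
label swap; its slope equals βW exactly, and R² is the uncentered
1 − SSres/Σy². Decile means can be back-transformed to raw units (e.g. an
IQ-like mean 100/SD 15 scale) from stored standardization parameters.

## GRM sensitivity model

To check that cryptic relatedness *between* families does not drive βB, the
fixed effects are refit with a genome-wide random effect g ~ N(0, A σg²),
where A is the genetic relationship matrix
A_mn = (1/N) Σ_i (x_im − 2p_i)(x_in − 2p_i)/(2p_i(1−p_i)), allele
frequencies estimated from the sample (user-supplied frequencies accepted);
monomorphic variants are excluded with a count. Estimation rotates onto the
eigenbasis of A (dense eigendecomposition — target cohorts of a few
thousand individuals are comfortably desk-scale) and profiles σg²/σε² by
the same 1-D scheme; tiny negative eigenvalues are clipped at zero. The
model contains g only, no additional family intercept; with A = I it
reduces exactly to the plain regression, which the tests verify. No MZ
twins, multi-component GREML or heritability partitioning are in scope.

## The synthetic cohort generator

The simulator is the ground truth for every estimator. Per family it draws
two parents, mates them, and produces two DZ offspring by independent
meioses at L unlinked biallelic loci (dosage genotypes; no linkage,
recombination maps, X chromosome or mutation — the design needs only
Mendelian segregation and a weighted allele sum):

- **Loci and weights.** Base allele frequencies ~ U(freq_low, freq_high);
  weights ~ N(0, 1/(2 L p̄(1−p̄))) so the raw score has variance near 1.
  Scores are z-standardized, making the configured effects per-SD.
- **Transmission.** Each parent contributes one allele per locus;
  heterozygotes transmit the effect allele with probability ½. This alone
  yields the co-twin score correlation of 0.50 under random mating.
- **Assortative mating** pairs parents within subpopulation by rank on a
  noisy proxy u = √r·z + √(1−r)·e of their standardized genetic value, so
  the realized mate correlation ≈ r_mate (calibration verified by
  simulation); it propagates to a sibling correlation (1+r)/2 / (1+r/2)
  > 0.50, the signature used to detect assortative mating empirically.
- **Stratification.** Subpopulation frequencies follow Balding–Nichols
  Beta draws around the base frequency with divergence fst; each
  subpopulation also gets an environmental offset with SD strat_shift;
  mating stays within subpopulation.
- **Phenotypes.** outcome = beta_direct·z_twin + beta_nurture·z_midparent
  + c_shared·C + δ_subpop + e, and SES = lambda_ses·z_midparent +
  nu_ses·C + sigma_ses·u. Genetic nurture is mediated by the mid-parent
  score — the average of both parents — reflecting that transmitted and
  non-transmitted parental alleles both shape the family environment.
  Co-twins share C, δ and SES.

Defaults (n_families = 1000, L = 500, beta_direct = 0.3, no nurture,
c_shared = 0.5, sigma_e = 0.81, random mating, one subpopulation,
SES loadings 0.5/0.5/0.71) give outcome and SES variances near 1 with a
moderate familial share — a realistic scale for standardized developmental
outcomes. One global seed drives deterministically derived stage seeds;
identical configs are bit-identical.

**What the simulator does not emulate:** linkage disequilibrium and LD-aware
score construction, genotyping error and imputation uncertainty, selection
and participation bias, age/sex effect heterogeneity, MZ twins, or
multi-generation equilibrium under assortative mating (one parental
generation only, so mating-induced disequilibrium is first-generation).
Passing recovery tests therefore demonstrates correctness of the
estimators under the stated generative model, not the magnitude of any
real-cohort effect.

## Validation problem sizes

The simulation suites use cohorts of 1,000–2,500 twin pairs at 200 loci
with 100–200 replicate cohorts and 500 bootstrap replicates, and a single
5,000-family, 1,000-locus cohort for the sibling-correlation checks —
sizes chosen to pin each statistic well inside its tolerance while keeping
the whole suite a few minutes on a laptop. `scripts/acceptance.py --seed N
--out results/acceptance.json` regenerates the 5,000-family cohort and
reports the co-twin score correlation and shared-variance percentage.

## Numerical notes and edge cases

- Families without exactly two complete members are excluded with a count
  (strict mode raises); clusters of other sizes are an error, not silently
  supported.
- Zero outcome variance, fewer than `min_pairs` (default 10) pairs, an
  outcome reused as covariate, all-zero score differences, an empty
  weight/genotype variant intersection, and a GRM not covering the cohort
  are all hard errors with named messages.
- Degenerate bootstrap distributions (zero difference SD) raise rather than
  return infinite z.
- Residualization tolerates collinear covariates (minimum-norm solve,
  warning — residuals are unaffected) but rejects covariates that explain
  the variable exactly.
- Allele matching in scoring flips dosages (x → 2−x) when the weight's
  effect allele is the genotype's other allele, and drops strand-ambiguous
  A/T and G/C flips rather than guessing; dropped and missing variants are
  counted in the scoring report.
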