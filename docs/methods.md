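# Methods

This note documents the statistical model behind `famassoc`, the
synthetic cohort the package is calibrated against, the numerical
choices, and the known limitations.

## Study design and data model

The package targets nuclear-family cohorts recruited as sibling pairs:
each family has two parents (recorded in the pedigree, often without
genotypes or phenotypes) and 2–3 phenotyped, genotyped siblings. Markers
form a small ordered panel within one gene — by default the four Gas6
(13q34) SNPs rs8191974, rs7323932, rs7331124, rs8191973, in that
haplotype coordinate order. Genotypes are unordered allele pairs; all
codings count the declared effect allele (the minor allele unless
overridden). Files travel as PLINK text PED/MAP plus a tab-separated
phenotype table keyed by individual id; missing alleles are "0", missing
phenotype cells empty or "NA".

## Phenotype derivation

* HOMA-IR = FPI (µU/ml) × FPG (mmol/l) / 22.5. Glucose reported in
  mg/dl is converted with the molar mass of glucose, 18.0182 mg/mmol
  (the conversion constant is a package choice; any fixed constant
  cancels out of rank-based and linear analyses).
* Obesity = BMI ≥ 30 kg/m² (boundary inclusive).
* Inactivity score s = sedentary hours / (24 − basal hours); sedentary
  lifestyle means s strictly greater than 0.5.
* T2D = FPG ≥ 126 mg/dl, or 2-h post-challenge glucose ≥ 200 mg/dl, or
  use of oral hypoglycemic agents; missing criteria are simply not
  evaluated, and the call is missing only if all three are.
* Right-skewed traits (FPI, HOMA-IR) are natural-log transformed before
  analysis. Natural rather than base-10 log is a package choice; the
  scale of a log base is absorbed by the regression coefficients and
  does not change test statistics.
* Trait residualization: the (transformed) trait is regressed by OLS on
  an intercept plus covariates over all phenotyped individuals, with
  categorical covariates (sex, site, ethnicity) expanded to treatment
  contrasts; the residuals are the trait fed to the family score test.
  Pooling across families at this stage is deliberate — within-family
  correlation is handled by the conditional test itself, not the
  residualization. Rank-deficient designs abort with the offending
  columns named.

## The conditional family score test

For offspring j of family i, residual T_ij and genotype code X_ij:

U = Σ_ij T_ij (X_ij − E[X_ij | C_i]), V = Σ_i T_i' Σ_i T_i, z = U/√V,
two-sided normal p (equivalently χ²₁ on z²).

Conditioning C_i:

* **Both parents genotyped.** The exact Mendelian transmission
  distribution of the offspring code given the parental genotype pair:
  each parent transmits each of its two alleles with probability 1/2,
  independently across offspring given parents, so Σ_i is diagonal with
  the per-offspring conditional variance. Offspring incompatible with
  their parents raise a Mendelian-inconsistency error naming the family.
* **No parent genotyped, ≥ 2 genotyped sibs.** Conditioning on the
  sufficient statistic — the observed multiset of sib codes. Under the
  null the codes are exchangeable across sibs, giving per-sib mean X̄,
  variance m₂ − X̄² (population moments of the multiset), and
  between-sib covariance −σ²/(n−1). The family variance contribution is
  σ² [Σ T² − ((ΣT)² − ΣT²)/(n − 1)].
* **Exactly one parent genotyped.** The family is dropped and counted in
  the result's family tally. Full single-parent sufficient-statistic
  conditioning is out of scope; with the default cohort (all or no
  parents typed) no family falls in this class.

Families with zero conditional variance contribute nothing;
`n_informative_families` counts those with positive variance. If the
total V is zero the result is flagged untestable rather than given a p.

Variants:

* **Conditional-on-top-SNP:** the trait is additionally residualized on
  the conditioning SNP's additive code before scoring.
* **Interaction:** the trait is residualized on covariates, the binary
  lifestyle factor E, and the marker's additive main effect; the score
  weights genotype deviations by (E_ij − Ē)·r_ij. With constant E the
  test is untestable. This concrete projection-based formulation is a
  package design choice among the several score-type interaction tests
  in the literature.
* **Haplotype dosage:** each individual's expected count of a target
  haplotype is the posterior mean over phase configurations with
  haplotype-frequency priors (from the EM fit). With genotyped parents
  the offspring dosage moments are obtained by enumerating parental
  phase configurations weighted by their posteriors and the four
  transmissions — including the between-sib covariance induced by the
  shared unknown phase; parentless sibships use the permutation
  conditioning on the sib dosages. An omnibus χ² combines all
  haplotypes with frequency ≥ 0.01 through the generalized inverse of
  the score covariance (the dosages sum to 2, so the covariance is
  rank-deficient by construction and the df equals its rank).

## Population-genetic components

* **Exact HWE test** conditions on the minor-allele count: P(h | n, m) ∝
  2^h n! / (n_AA! h! n_aa!) over the heterozygote support, two-sided by
  summing configurations no more probable than the observed one
  (probabilities computed with log-gamma; equality tolerance 1e-12
  relative). It runs on a one-per-family random subset because HWE
  assumes independent genotypes.
* **Haplotype EM** enumerates the 2^(k−1) phase pairs per k-heterozygous
  genotype, weights pairs by f_h1 f_h2 (×2 for distinct haplotypes),
  and iterates to max |Δf| < tol (default 1e-8, cap 2000 iterations,
  warning on non-convergence). Initialization is the
  linkage-equilibrium product of allele frequencies, with an optional
  seeded jitter for robustness checks; ties between phase pairs split
  weight exactly. Individuals with any missing genotype are excluded
  (the call rate is reported alongside so the exclusion is visible).
* **LD**: D = f_AB − p_A p_B and r² = D²/(p_A q_A p_B q_B) marginalized
  from the haplotype table. Note a haplotype-table r² and a
  genotype-correlation r² (as in common LD-plot software) are different
  estimators and agree only approximately.

## GEE effect estimates

Marginal models are fitted with statsmodels' GEE, exchangeable working
correlation, clusters = families, and sandwich (robust) covariance;
with singleton clusters the sandwich reduces to HC0 heteroskedasticity-
robust OLS, which the tests verify. Genotype enters either as category
indicators (per-genotype odds ratios, adjusted means) or as a numeric
code (trend and stratified effects). Adjusted means use the
least-squares-means covariate profile — continuous covariates at the
analysis-sample means, categorical indicators at observed proportions —
with delta-method SEs and 1.96-quantile 95% CIs. Analyses are complete-
case; empty genotype categories are omitted from output. Logistic fits
with |coefficient| > 15 are treated as separated and raise.

## Resampling procedures

**Min-p adjustment.** All genotypes (founders and offspring) are
regenerated in each null replicate: founder haplotype pairs i.i.d. from
the estimated haplotype table, offspring by gene dropping with no
recombination across the panel, and the observed per-individual,
per-SNP missingness mask re-applied — family structures, trait values,
and covariates are untouched, preserving trait correlations and marker
LD under the null. Adjusted p = #{r : m_r < p_i}/R with strict
inequality and no smoothing, exactly the counting definition (a
(#+1)/(R+1) variant is available behind a flag). Untestable tests
inside a replicate contribute p = 1 to that replicate's minimum
(conservative). The replicate battery is computed by a vectorized
engine whose per-replicate p-values are verified against the
object-level test to 1e-12 in the suite.

**Family bootstrap power.** Families resampled with replacement to the
original count; each replicate re-residualizes the trait and reruns the
score test; power = #{p < α}/B, untestable replicates counted as
non-rejections. Because resampling preserves the observed
trait-genotype pairing, the bootstrap statistic is centered at the
observed cohort z: the procedure estimates power *at the observed
effect*. Consequence (documented deliberately): at a truly null marker
the estimate is close to α only when the cohort's chance association is
itself near zero; averaged over null cohorts it sits near
P(|N(ẑ,1)| > 1.96) ≈ 0.17. The suite therefore checks the null behavior
both as literally defined on a fixed cohort and as an ensemble-average
monotonicity property over an effect grid.

**SSPG case/control haplotype OR.** Threshold = 75th percentile
(linear-interpolation quantile) of all observed SSPG; cases strictly
above. One random case per family containing a case, one random control
per all-control family (so the set is unrelated). The 2×2 table of
posterior-expected target/reference haplotype counts gives the
cross-product OR with a Woolf log-OR CI; zero cells trigger a flagged
0.5 continuity correction.

## The synthetic cohort generator

The generator is the package's study condition, not a convenience
fixture. Defaults: 440 nuclear families with 2 sibs (77%) or 3 sibs
(23%), ≈ 980 phenotyped siblings; parents carried in the pedigree but
ungenotyped and unphenotyped by default (`parent_genotype_missing_rate`
= 1.0 — the sib-pair recruitment design; set it to 0 to exercise
parental conditioning). Founder chromosomes come from the 14-haplotype
table with frequencies (0.4258 G-A-C-G … 0.0035 G-A-T-C) summing to
exactly 1; transmission is haplotype-wise with no recombination, as
appropriate for a 4-SNP panel within one gene.

Covariates are drawn from the reference cohort's marginals: age
N(49.5, 8.8²), BMI N(25.5, 3.72²) (obesity is derived from BMI, giving
≈ 11.3% prevalence), 44% male, smoking 17.3%, alcohol 28.7%,
hypertension 65.2%, ethnicity Chinese 77.9%/Japanese 22.1%, three sites
(family-level, so sibs share site and ethnicity). The inactivity score
is Beta(2, b) with b solved so that P(s > 0.5) matches the 66.7%
sedentary fraction; basal hours are fixed at 8 and sedentary hours are
16·s. Only the marginals are calibrated — the joint covariate law is
independence (plus the site/ethnicity family sharing), because the
reference tables publish marginals only.

Trait models: continuous traits follow β₀ + β_g·X + Σβ_c·c + β_ge·X·E +
b_family + ε with b ~ N(0, σ_f²), ε ~ N(0, σ_e²); binary traits use a
logistic link on the same linear predictor; `log_scale` simulates on
the log scale and exponentiates (FPI: exp N(1.788, 0.697²), matching
mean ≈ 7.6 and SD ≈ 6.0). The default SSPG model (intercept 60.7, age
0.8, BMI 2.5, per-C-allele effect 12 mg/dl at rs8191973, σ_f = 30,
σ_e = 60) reproduces mean ≈ 168 and SD ≈ 68 mg/dl. Incident T2D has
logit intercept −1.607 (rate ≈ 0.167) and no genetic effect by
default. SSPG and follow-up observation fractions are configurable
(default 1.0; the reference design measured SSPG in a ~22% subset and
followed ~53%, reproducible by setting the fractions).

What the generator does *not* emulate — and hence what passing tests do
not certify about real data: ascertainment on hypertension concordance,
genotyping error, covariate-covariate dependence beyond family-shared
site/ethnicity, parental phenotypes, multi-generation pedigrees, and
recombination.

## Problem sizes and numerical choices in the verification suite

The statistical acceptance checks use sizes chosen as sensible study
conditions: type-I error from 2000 null replicates of 200 families per
coding and conditioning policy (band 0.035–0.065 at α = 0.05);
family-wise error of the min-p adjustment from 200 outer null cohorts
of 120 families with R = 500 inner replicates (3-binomial-SE band
around 0.05); GEE coverage and score-test sign recovery over 100
cohorts of 150 families at a per-allele effect of 20 mg/dl; bootstrap
monotonicity over effects {0, 10, 20, 40} mg/dl averaged over 6 cohorts
per point; EM recovery from 5000 simulated founders (3 Monte-Carlo SE ≈
0.021 tolerance on the major haplotype). The vectorized replicate
engine makes each of these a few seconds to a couple of minutes of
single-CPU work.

Other numerics: two-sided normal reference for z (no small-sample exact
p-values); permutation variance uses population (1/n) moments; EM
frequencies renormalized after convergence to remove accumulated float
error; pseudoinverse tolerance 1e-10 for the omnibus; random draws all
via numpy Generator seeded explicitly, and every pipeline stage records
its seed in the manifest so reruns are byte-identical.

## Known limitations

* One-parent families are dropped rather than conditioned on their
  sufficient statistic.
* The haplotype dosage test relies on EM frequency priors; with very
  rare target haplotypes the dosage variance is small and tests are
  conservative (flagged untestable at zero frequency).
* The bootstrap power estimator inherits the observed-effect centering
  discussed above; it is a power-at-the-observed-cohort estimate, not a
  nominal-level diagnostic.
* GEE assumes an exchangeable working correlation; misspecification
  costs efficiency though the sandwich keeps inference valid.
* The generator's covariate independence understates real confounding;
  stratification-robustness of the score test is by construction, not
  demonstrated against simulated admixture.
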