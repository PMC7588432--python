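# Methods

## The statistical model

The central quantity is the conditional association between a parental
genetic risk score (GRS) and an offspring cardiometabolic outcome.  For a
set of analysis pairs the outcome vector y (one row per offspring,
z-scored within the analysis sample) is modelled as

    y ~ N(X beta, A sigma_g^2 + I sigma_e^2)

where X contains an intercept, the exposure GRS (maternal or paternal),
the conditioning GRS (offspring), and age, sex and measurement occasion;
A is a genetic relationship matrix (GRM) over the offspring, which absorbs
both sibship structure and cryptic relatedness.  Exactly two variance
components are fitted, one of them a residual component uncorrelated
across individuals.

Estimation is full-information maximum likelihood (ML rather than REML,
deliberately: log-likelihoods must be comparable across fixed-effect
specifications, since inference is by likelihood-ratio tests against a
sub-model with the tested coefficient fixed at zero).  Writing
A = U diag(d) U', premultiplying y and X by U' leaves independent
observations with variances v_i = d_i sigma_g^2 + sigma_e^2, so the
likelihood factorizes and no N x N inversion is needed.  Given the ratio
delta = sigma_g^2/sigma_e^2, beta is weighted least squares with weights
1/(d_i delta + 1) and sigma_e^2 has a closed form; the fit is a 1-D
search over log(delta).

### Numerical choices

* log(delta) is scanned on a 33-point grid over [-8, 8], the best
  bracket refined by bounded scalar minimization (xatol 1e-12); the
  boundary sigma_g^2 = 0 is always evaluated as a candidate, so boundary
  solutions are exact rather than asymptotic.
* sigma_g^2 is constrained >= 0.  When A is (numerically) proportional to
  I the split is unidentifiable; the fit then reports the total variance
  in sigma_e^2, sets sigma_g^2 = 0 and flags `identifiable_ = False`.
  Passing no relatedness structure at all selects this independence mode
  explicitly; the replicate studies below use it for cohorts simulated
  without any polygenic background, where A = I is the truth and a
  per-replicate eigendecomposition would change nothing.
* GRM eigenvalues below zero are clamped to 0 (warning if below -1e-8);
  eigenvector sign and ordering provably do not affect any reported
  statistic (tested).
* Likelihood-ratio statistics are clamped at 0; a sub-model beating the
  full model by more than 1e-6 raises, since that indicates non-nesting
  or optimizer failure.  Wald SEs are reported alongside LRT p-values.
* Agreement between a fit and the same fit after jointly permuting rows
  holds to 1e-8 on beta; variance components agree to ~1e-7, the limit
  set by round-off in two independent eigendecompositions.
* Rows with a missing outcome, covariate or score are dropped listwise
  before the GRM is subset and decomposed, so each analysis decomposes
  the matrix for exactly its own sample.

## Scores, kinship and QC

GRSs are unweighted sums of birthweight-increasing-allele dosages: the
per-allele effect on growth restriction is unknown, so weighting by
observed birthweight effects would impose the wrong metric.  Missing
dosages are mean-imputed (2 x sample frequency of the increasing allele);
an individual missing more than 10% of a panel gets a missing score.
Allele frequencies for imputation and GRM standardization are computed in
the analysis sample.

The GRM uses the standardized-product formula (1/m) sum_i
(x_ij - 2p_i)(x_ik - 2p_i) / (2p_i(1-p_i)), with the same form on the
diagonal — only the offspring-offspring covariance structure matters here
and the simple form keeps the matrix PSD up to noise.  SNPs within 1 Mb
of any score SNP (inclusive) are excluded so that score signal is not
absorbed into the random effect.

Kinship is the KING-robust estimator from hard-called (rounded) dosages,
with the symmetric denominator N_het(i) + N_het(j), so estimates do not
depend on pair order.  Degrees use the 2^(-1/2)-spaced cutoffs
(0.354 / 0.177 / 0.0884 / 0.0442); first-degree pairs split into
parent-offspring vs full-sibling at IBS0 < 0.005.  Analysis pairs assign
the older member the parent role, remove pairs with birth-year gaps of
15 years or fewer (ties excluded), and let a parent appear once per
offspring.  Sample QC removes heterozygosity outliers beyond +/-5 SD and
individuals flagged sex-mismatched in metadata (genetic sex inference
needs X-chromosome data and is out of scope); variant QC removes
MAF < 0.005 or missingness > 5%, both bounds strict.

## Phenotype preparation

SBP/DBP are the mean of the second and third readings (second alone when
only two exist; fewer than two is missing), with +15/+10 mmHg added for
self-reported antihypertensive users *after* averaging — adjustment
rather than a covariate avoids collider bias.  LDL is Friedewald in
mmol/L (TC - HDL - TG/2.2; the 2.2 divisor is the mmol/L convention of
the formula; no high-TG suppression ceiling is applied).  Glucose, TG and
BMI are natural-log transformed; every analysis variable is then trimmed
once — never iterated — at 4 SD from the post-transform mean, computed in
the analysis sample.  Birthweight models additionally exclude multiple
births, congenital malformations, induced or C-section deliveries,
birthweight under 1000 g and gestation under 258 days; missing registry
flags count as eligible (logged).  Age strata are half-open, [20, 40) and
[40, 60), following the prose convention ("under 40") where prose and
table labels conflict at the boundary; 60+ is not analysed.  No
multiple-testing correction is applied anywhere.

## The simulator

The generator emulates the study conditions the analysis assumes:

* **Genotypes.** Unlinked biallelic SNPs (the score panels are
  independent genome-wide-significant loci, so linkage is irrelevant to
  the tested quantities), frequencies uniform on (0.1, 0.9), parents
  Binomial(2, p) under random mating, Mendelian transmission
  (heterozygote transmits the counted allele with probability 1/2),
  siblings sharing both parents.  Default panel sizes 31 maternal-only +
  40 maternal+fetal + 133 fetal-only score SNPs (204 total, 71 with any
  maternal effect) plus 200 background SNPs.
* **Latent scale.** A scalar standardized latent intrauterine factor
  U = gamma z(GRS_m) + e; standardized birthweight lambda1 U + direct
  fetal effects + disturbance; standardized outcome lambda2 U + fetal
  pleiotropy + background-SNP polygenic component + disturbance, with
  disturbance covariance theta.  The polygenic component is built from
  actual background SNPs (variance fraction `polygenic_h2`, default 0.2)
  rather than a family-structured normal draw, so GRM estimation is
  exercised end to end.  Defaults gamma=0.1414, lambda1=-0.5,
  lambda2=0.1, theta=0 are the worked variance-decomposition example;
  fetal variance fractions default to 2% (birthweight) and 1% (outcome),
  plausible for genome-wide-significant panels.
* **Measurements.** Latent SBP = 125 + 15 x outcome SD; three readings
  with 3 mmHg noise and an elevated first reading; 12% of individuals
  have only two readings; medicated individuals (15%) have *stored*
  readings 15/10 mmHg below their latent value, so the pipeline's
  adjustment rule is genuinely exercised.  Glucose/TG/BMI are log-normal;
  TC/HDL normal.  Birth years place parents 25-40 years above their first
  offspring, with a 2% fraction of 10-year gaps to exercise the pair
  filter; offspring born before 1967 have no registry record (missing
  birthweight), and registry flags are drawn at survey-typical rates.
  One generator (PCG64, single seed) governs genotypes; phenotypes use an
  independent stream at seed+1 so the two stages are separately
  reproducible.
* **Offspring-count distribution.** Families carry 1-8 offspring; the
  published material states only the range, so the default distribution
  (0.45, 0.35, 0.13, 0.05, 0.01, 0.005, 0.003, 0.002) is a free choice
  roughly matching completed-fertility shapes in Nordic registries.

What the simulator does *not* emulate: X-chromosome transmission,
genotyping error, imputation uncertainty, population stratification,
assortative mating, LD, or age-dependent effect sizes.  Passing tests
therefore show that the pipeline is calibrated and unbiased *under the
assumed generative model*, not that real-data confounders are handled.

## Power and path algebra

The conditional test's noncentrality is ncp = N q^2 (1 - r^2): q^2 the
marginal outcome-variance fraction explained by the tested GRS, r the
correlation between tested and conditioning GRS (0.5 for parent-offspring
under random mating), the (1 - r^2) factor the collinearity penalty.
Power is P[chi^2_1(ncp) > chi^2_1 critical at alpha], a two-sided test in
chi-square form (the negligible second normal tail is retained).  This
model reproduces every published power figure for the design (79.8%,
68.3%, 78.9%, 67.3%, 80.7%, 66.3% at the respective N and q^2), which is
the validation of the (1 - r^2) deflation — it was adopted because it
reproduces those figures, not assumed.  The smallest detectable q^2
inverts the power curve by bracketed root-finding (relative tolerance
1e-8).

Path algebra on the standardized scale: variance of birthweight explained
by the maternal GRS = gamma^2 lambda1^2; of the outcome =
gamma^2 lambda2^2; implied birthweight-outcome correlation =
lambda1 lambda2 + theta.  Note that gamma = 0 alone does *not* zero the
birthweight-outcome correlation — the latent factor still links them with
lambda1 lambda2 — so the "all pathways off" null requires
lambda1 lambda2 = theta = 0 as well.

## Replicate studies (`triomr.validation`)

* **Type-I error under pure fetal pleiotropy:** 500 replicate cohorts of
  2,000 independent mother-offspring pairs, offspring SNPs explaining 5%
  of outcome variance, no maternal path; the maternal conditional test's
  rejection rate is compared with alpha within two binomial SEs.  This is
  the design's core identification property: conditioning on the
  offspring GRS blocks the transmission-induced association.
* **Effect recovery:** 150 replicates with a ~0.02 per-allele maternal
  effect (|mean bias| < 0.2 of the average SE) and 300 replicates at a
  smaller effect placed where power is moderate, compared with the
  analytic calculator within two binomial SEs.  The truth value accounts
  for two features of the measurement chain: the score's
  birthweight-increasing orientation is anti-aligned with the latent
  factor when gamma lambda1 < 0, and averaging noisy BP readings
  attenuates the variance fraction by signal/(signal + measurement
  variance) (~0.978 at the default settings).
* Replicates use independent one-offspring families with no polygenic
  background, fitted in independence mode; the GRM path is covered by
  the sibship variance-component recovery and rotation-equivalence tests.
  Problem sizes (2,000 pairs, 150-500 replicates, N=50 for the direct
  N x N likelihood oracle) were chosen to keep each study's Monte-Carlo
  error comfortably inside its acceptance band.

## Known limitations

* The mixed model fits one outcome at a time; no multivariate or
  repeated-measures support.
* Kinship all-pairs mode is dense O(n^2 m); fine to a few thousand
  samples, not biobank scale.
* The Friedewald formula is applied at all TG levels; real pipelines
  often suppress LDL above ~4.5 mmol/L TG.
* Formal instrumental-variable effect estimation (two-stage or ratio
  estimators) is deliberately out of scope; the package tests and powers
  the conditional association design.
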