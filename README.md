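# triomr

Family-based Mendelian randomization of intrauterine effects on later-life
cardiometabolic risk.

## The problem

The Developmental Origins of Health and Disease (DOHaD) hypothesis holds
that an adverse intrauterine environment — proxied by reduced fetal growth —
raises the offspring's cardiometabolic risk decades later.  The observational
birthweight–risk-factor correlation cannot settle this, because the same
fetal genotypes influence both birthweight and adult metabolic traits
(pleiotropy), and families share environments.  A family-based design breaks
the confounding: maternal alleles that influence offspring birthweight act on
the fetus *through the intrauterine environment* for the untransmitted half
of the maternal genome, so a maternal genetic risk score (GRS), conditioned
on the offspring's own GRS, is a clean instrument for intrauterine exposure.
A paternal GRS conditioned the same way serves as a negative control for
postnatal (dynastic) effects.

`triomr` implements the full analysis machinery for this design, for
statistical geneticists and epidemiologists who want to run, calibrate or
power such a study:

* **`triomr.simulate`** — genotyped mother–father–offspring trios under an
  explicit standardized path model: maternal GRS → latent intrauterine
  factor *U* (path γ), *U* → birthweight (λ₁) and → outcome (λ₂), residual
  covariance Θ, direct fetal effects, a background-SNP polygenic component,
  sibships, and the raw survey artifacts (triplicate BP readings, medicated
  readings stored unadjusted, non-normal glucose/TG/BMI, birth-registry
  flags, missingness).
* **`triomr.qc`** — heterozygosity/sex-mismatch sample QC, MAF/missingness
  variant QC, KING-robust kinship, relationship classification, and the
  parent–offspring pair set (birth-year gap > 15 years).
* **`triomr.scores`** — unweighted birthweight GRSs (204/71/31-SNP panels in
  the simulator's default layout), the GCTA-style GRM with a 1 Mb exclusion
  zone around score SNPs, and its eigendecomposition.
* **`triomr.lmm`** — the core model: a two-variance-component FIML linear
  mixed model, y ~ N(Xβ, **A**σ²_g + **I**σ²_e), computed through the
  spectral rotation of **A** so the likelihood factorizes over individuals
  (an `EigenLMM` scikit-learn estimator), with likelihood-ratio tests for
  fixed effects.
* **`triomr.pipeline`** — phenotype cleaning (BP averaging with the +15/+10
  mmHg medication adjustment, Friedewald LDL, log-then-trim at 4 SD,
  registry exclusions) and the three analysis families: phenotypic
  birthweight models, conditional GRS models, and age-stratified models.
* **`triomr.power`** — analytic power for conditional GRS tests via the
  noncentral χ²(1) with ncp = N·q²·(1−r²), and the path-model variance
  algebra (γ²λ₁² of birthweight variance, γ²λ₂² of outcome variance,
  implied correlation λ₁λ₂ + Θ).

## Worked example

Simulate a 1,000-family cohort and run the maternal conditional analysis:

```
$ triomr simulate --out demo --seed 4
wrote 3894 individuals (1000 families, 1894 offspring), 404 SNPs

$ triomr fit-grs --cohort demo --outcome sbp --outcome glucose --out demo/grs.tsv
outcome     score_set exposure conditioning stratum  effect       se        p    n
    sbp all_autosomal maternal    offspring     all 0.00599 0.002812 0.033279 1894
glucose all_autosomal maternal    offspring     all 0.00582 0.002970 0.050143 1847
```

Effects are standardized-outcome units per birthweight-increasing allele of
the maternal GRS, conditioned on the offspring GRS and adjusted for age,
sex and measurement occasion; p-values are −2·Δlog-likelihood χ²(1) tests.
Under the default generative model (γ = 0.1414, λ₂ = 0.1) the true maternal
conditional effect is small (≈0.003 per allele), so at 1,894 pairs single
runs hover around nominal significance — exactly the power regime the
calculator quantifies:

```
$ triomr power --n 26057 --q2 0.0004
n=26057 q2=0.0004 alpha=0.05 r=0.5 power=0.7984

$ triomr power --n 26057 --invert --power 0.8
n=26057 alpha=0.05 power=0.8 r=0.5 q2_min=0.000401625
```

At 26,057 pairs the conditional design has 80% power for a maternal effect
explaining 0.04% of outcome variance.  The path algebra shows how small
that is in mechanistic terms:

```
$ triomr pathmodel --q2-bw 0.005 --lambda1 -0.5 --lambda2 0.1
gamma=0.1414
bw_variance_explained=0.005
outcome_variance_explained=0.0002
implied_bw_outcome_correlation=-0.05
```

A maternal GRS explaining 0.5% of birthweight variance through a latent
factor with a −0.5 loading implies γ = 0.1414; if that factor moves the
outcome with λ₂ = 0.1, the GRS explains only 0.02% of outcome variance,
and the model implies a birthweight–outcome correlation of −0.05.

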