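"""Simulation of genotyped mother-father-offspring trios.

The generative model is a single-latent-factor path model: an oriented
maternal genetic risk score (GRS) loads on a latent intrauterine factor U
with path coefficient ``gamma``; U in turn affects offspring birthweight
(path ``lambda1``) and an offspring cardiometabolic outcome (path
``lambda2``).  Offspring genotypes may additionally carry direct (fetal)
effects on birthweight and pleiotropic effects on the outcome, plus a
polygenic outcome component built from background SNPs so that genomic
relatedness genuinely carries signal.  All latent-scale variables are
standardized to unit variance; ``theta`` is the residual covariance
between the birthweight and outcome disturbances.

On top of the latent scale the simulator emits the raw measurement
artifacts a population-survey pipeline has to clean: three blood-pressure
readings per visit (with an elevated first reading), antihypertensive-
medication users whose *stored* readings are the treated, unadjusted ones,
non-normal glucose / triglyceride / BMI distributions, birth-registry
exclusion flags, pre-registry-era missing birthweights, and sporadic
missingness in the biochemistry.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "SNPRecord", "SimConfig", "TrioCohort", "ConfigurationError",
    "simulate_genotypes", "simulate_phenotypes", "simulate_cohort",
    "score_definitions",
]

#: survey year used to convert birth years to ages, per measurement occasion
SURVEY_YEARS = {2: 1996, 3: 2007}

PHENOTYPE_COLUMNS = [
    "sbp1", "sbp2", "sbp3", "dbp1", "dbp2", "dbp3", "bp_med",
    "glucose", "tc", "hdl", "tg", "weight_kg", "height_m",
    "birthweight_g", "gestation_days", "csection_or_induced",
    "multiple_birth", "malformation", "age", "sex", "occasion",
]


class ConfigurationError(ValueError):
    """Raised when a simulation configuration is internally inconsistent."""


@dataclass
class SNPRecord:
    """One biallelic SNP: position, counted-allele frequency and effects.

    Effects are on the standardized latent scale, per counted allele.
    ``maternal_bw_effect`` is the effect routed through the latent
    intrauterine factor; ``fetal_bw_effect`` and ``fetal_pleiotropy`` are
    direct offspring-genotype effects on birthweight and outcome.
    """

    snp_id: str
    chromosome: int
    position: int
    counted_allele: str
    other_allele: str
    freq: float
    effect_class: str = "background"  # maternal_only | fetal_only | both | background
    maternal_bw_effect: float = 0.0
    fetal_bw_effect: float = 0.0
    fetal_pleiotropy: float = 0.0


@dataclass
class SimConfig:
    """Study conditions for the trio simulator.

    Path coefficients default to the standardized values of the worked
    variance-decomposition example (maternal GRS explaining 0.5% of
    birthweight variance with a factor-to-birthweight path of -0.5):
    gamma=0.1414, lambda1=-0.5, lambda2=0.1, theta=0.  Score-SNP counts
    default to the three nested birthweight score panels (31 maternal-only,
    40 maternal+fetal, 133 fetal-only; 204 in total, 71 with any maternal
    effect).
    """

    n_families: int = 1000
    #: distribution of offspring count per family over 1..8
    offspring_dist: Mapping[int, float] = field(default_factory=lambda: {
        1: 0.45, 2: 0.35, 3: 0.13, 4: 0.05, 5: 0.01, 6: 0.005,
        7: 0.003, 8: 0.002,
    })
    n_maternal_only: int = 31
    n_maternal_fetal: int = 40
    n_fetal_only: int = 133
    n_background_snps: int = 200
    freq_range: tuple[float, float] = (0.1, 0.9)
    # path model (standardized scale)
    gamma: float = 0.1414
    lambda1: float = -0.5
    lambda2: float = 0.1
    theta: float = 0.0
    fetal_bw_h2: float = 0.02
    fetal_pleiotropy_h2: float = 0.01
    polygenic_h2: float = 0.2
    genotype_missing_rate: float = 0.0
    # phenotype-collection artifacts
    offspring_birth_years: tuple[int, int] = (1937, 1988)
    close_gap_fraction: float = 0.02   # families with a <=15 y parent-offspring gap
    male_fraction: float = 0.484
    bp_med_prevalence: float = 0.15
    p_three_bp_readings: float = 0.88
    sbp_reading_sd: float = 3.0
    dbp_reading_sd: float = 2.5
    p_occasion3: float = 0.65
    multiple_birth_rate: float = 0.012
    malformation_rate: float = 0.018
    csection_induced_rate: float = 0.14
    gestation_mean: float = 282.0
    gestation_sd: float = 11.0
    biochem_missing_rate: float = 0.02
    seed: int = 0

    # -- validation ------------------------------------------------------
    def validate(self) -> None:
        if self.n_families <= 0:
            raise ConfigurationError("n_families must be positive")
        lo, hi = self.freq_range
        if not (0.0 < lo < hi < 1.0):
            raise ConfigurationError("freq_range must satisfy 0 < lo < hi < 1")
        if self.n_score_snps <= 0:
            raise ConfigurationError("at least one score SNP is required")
        if not all(1 <= k <= 8 for k in self.offspring_dist):
            raise ConfigurationError("offspring counts must lie in 1..8")
        if abs(sum(self.offspring_dist.values()) - 1.0) > 1e-8:
            raise ConfigurationError("offspring_dist must sum to 1")
        for name in ("fetal_bw_h2", "fetal_pleiotropy_h2", "polygenic_h2"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must lie in [0, 1]")
        if abs(self.gamma) > 1 or abs(self.lambda1) > 1 or abs(self.lambda2) > 1:
            raise ConfigurationError("path coefficients must lie in [-1, 1]")
        if abs(self.lambda1 * self.lambda2 + self.theta) > 1:
            raise ConfigurationError("implied birthweight-outcome correlation outside [-1, 1]")
        v_bw = 1.0 - self.lambda1 ** 2 - self.fetal_bw_h2
        v_out = (1.0 - self.lambda2 ** 2 - self.fetal_pleiotropy_h2
                 - self.polygenic_h2)
        if v_bw < 0 or v_out < 0:
            raise ConfigurationError("implied residual variance is negative")
        if abs(self.theta) > np.sqrt(v_bw * v_out) + 1e-12:
            raise ConfigurationError(
                "theta exceeds the residual covariance bound sqrt(v_bw*v_out)")

    @property
    def n_score_snps(self) -> int:
        return self.n_maternal_only + self.n_maternal_fetal + self.n_fetal_only

    def residual_variances(self) -> tuple[float, float]:
        """(birthweight, outcome) disturbance variances implied by the paths."""
        return (1.0 - self.lambda1 ** 2 - self.fetal_bw_h2,
                1.0 - self.lambda2 ** 2 - self.fetal_pleiotropy_h2
                - self.polygenic_h2)


@dataclass
class TrioCohort:
    """Genotypes, pedigree and raw phenotypes for a set of trio families.

    ``dosages`` holds one row per individual (mothers, fathers and
    offspring together, indexed by individual_id) and one column per
    snp_id, values in [0, 2] with NaN for missing.  Role-specific views
    are available through :meth:`role_dosages`.
    """

    dosages: pd.DataFrame
    snp_table: pd.DataFrame
    pedigree: pd.DataFrame
    phenotypes: pd.DataFrame | None = None
    config: SimConfig | None = None
    #: per-offspring latent variables (u, bw_std, outcome_std) kept in
    #: memory for diagnostics; never written to disk
    latents: pd.DataFrame | None = None

    def role_dosages(self, role: str) -> pd.DataFrame:
        ids = self.pedigree.loc[self.pedigree["role"] == role, "individual_id"]
        return self.dosages.loc[ids]

    @property
    def mothers(self) -> pd.DataFrame:
        return self.role_dosages("mother")

    @property
    def fathers(self) -> pd.DataFrame:
        return self.role_dosages("father")

    @property
    def offspring(self) -> pd.DataFrame:
        return self.role_dosages("offspring")

    @property
    def n_individuals(self) -> int:
        return len(self.dosages)

    def validate(self) -> None:
        if list(self.dosages.columns) != list(self.snp_table["snp_id"]):
            raise ValueError("dosage columns do not match the SNP table")
        if set(self.dosages.index) != set(self.pedigree["individual_id"]):
            raise ValueError("dosage rows do not match the pedigree")


# ---------------------------------------------------------------------------
# genotypes

def _make_snp_table(config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    n = config.n_score_snps + config.n_background_snps
    lo, hi = config.freq_range
    freqs = rng.uniform(lo, hi, size=n)
    chroms = rng.integers(1, 23, size=n)
    positions = np.empty(n, dtype=np.int64)
    for c in np.unique(chroms):
        m = chroms == c
        # unique positions within a chromosome
        pos = rng.choice(np.arange(1, 250_000_000, 1000), size=m.sum(),
                         replace=False)
        positions[m] = np.sort(pos)
    bases = np.array(list("ACGT"))
    a1 = rng.integers(0, 4, size=n)
    a2 = (a1 + rng.integers(1, 4, size=n)) % 4

    classes = (["maternal_only"] * config.n_maternal_only
               + ["both"] * config.n_maternal_fetal
               + ["fetal_only"] * config.n_fetal_only
               + ["background"] * config.n_background_snps)
    table = pd.DataFrame({
        "snp_id": [f"rs{900000 + i}" for i in range(n)],
        "chromosome": chroms,
        "position": positions,
        "counted_allele": bases[a1],
        "other_allele": bases[a2],
        "freq": freqs,
        "effect_class": classes,
        "maternal_bw_effect": 0.0,
        "fetal_bw_effect": 0.0,
        "fetal_pleiotropy": 0.0,
    })

    # direct fetal effects, sized so each class explains its target variance
    is_fetal = table["effect_class"].isin(["both", "fetal_only"]).to_numpy()
    het = 2 * freqs * (1 - freqs)
    m_fet = int(is_fetal.sum())
    if m_fet and config.fetal_bw_h2 > 0:
        beta = np.sqrt(config.fetal_bw_h2 / (m_fet * het[is_fetal]))
        table.loc[is_fetal, "fetal_bw_effect"] = beta * rng.choice([-1.0, 1.0], m_fet)
    if m_fet and config.fetal_pleiotropy_h2 > 0:
        pi = np.sqrt(config.fetal_pleiotropy_h2 / (m_fet * het[is_fetal]))
        table.loc[is_fetal, "fetal_pleiotropy"] = pi * rng.choice([-1.0, 1.0], m_fet)

    # bookkeeping: per-allele maternal effect implied by the GRS-level path
    is_mat = table["effect_class"].isin(["maternal_only", "both"]).to_numpy()
    sd_grs = np.sqrt(het[is_mat].sum())
    if sd_grs > 0:
        table.loc[is_mat, "maternal_bw_effect"] = (
            config.gamma * config.lambda1 / sd_grs)
    return table


def _transmit(parent: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """One transmitted counted-allele count per parental genotype (0/1/2)."""
    out = (parent == 2).astype(np.int64)
    het = parent == 1
    out[het] = rng.integers(0, 2, size=int(het.sum()))
    return out


def simulate_genotypes(config: SimConfig) -> TrioCohort:
    """Draw parental genotypes under random mating and transmit to offspring.

    Parents are Binomial(2, freq) at every SNP; each offspring receives one
    allele from each parent, a heterozygous parent transmitting the counted
    allele with probability 1/2.  Siblings share both parents.  Returns a
    cohort with genotypes and pedigree only (phenotypes unset).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    snp_table = _make_snp_table(config, rng)
    freqs = snp_table["freq"].to_numpy()
    n_fam, n_snp = config.n_families, len(snp_table)

    counts = np.array(sorted(config.offspring_dist))
    probs = np.array([config.offspring_dist[k] for k in counts], dtype=float)
    n_off = rng.choice(counts, size=n_fam, p=probs / probs.sum())

    g_m = rng.binomial(2, freqs, size=(n_fam, n_snp))
    g_f = rng.binomial(2, freqs, size=(n_fam, n_snp))

    fam_of_off = np.repeat(np.arange(n_fam), n_off)
    g_o = (_transmit(g_m[fam_of_off], rng) + _transmit(g_f[fam_of_off], rng))

    # pedigree with birth years
    by_lo, by_hi = config.offspring_birth_years
    off_by = rng.integers(by_lo, by_hi + 1, size=len(fam_of_off))
    first_by = np.full(n_fam, by_hi)
    np.minimum.at(first_by, fam_of_off, off_by)
    mother_by = first_by - rng.integers(25, 41, size=n_fam)
    father_by = first_by - rng.integers(25, 41, size=n_fam)
    close = rng.random(n_fam) < config.close_gap_fraction
    mother_by[close] = first_by[close] - 10
    father_by[close] = first_by[close] - 10

    rows = []
    off_ptr = 0
    for fam in range(n_fam):
        fid = f"F{fam:05d}"
        rows.append((fid, f"{fid}_M", "mother", "F", int(mother_by[fam])))
        rows.append((fid, f"{fid}_P", "father", "M", int(father_by[fam])))
        for k in range(n_off[fam]):
            sex = "M" if rng.random() < config.male_fraction else "F"
            rows.append((fid, f"{fid}_O{k + 1}", "offspring", sex,
                         int(off_by[off_ptr])))
            off_ptr += 1
    pedigree = pd.DataFrame(
        rows, columns=["family_id", "individual_id", "role", "sex", "birth_year"])

    ids_m = pedigree.loc[pedigree.role == "mother", "individual_id"].to_numpy()
    ids_f = pedigree.loc[pedigree.role == "father", "individual_id"].to_numpy()
    ids_o = pedigree.loc[pedigree.role == "offspring", "individual_id"].to_numpy()
    dosages = pd.DataFrame(
        np.vstack([g_m, g_f, g_o]).astype(float),
        index=np.concatenate([ids_m, ids_f, ids_o]),
        columns=snp_table["snp_id"].to_numpy(),
    )
    dosages = dosages.loc[pedigree["individual_id"]]
    dosages.index.name = "individual_id"

    if config.genotype_missing_rate > 0:
        mask = rng.random(dosages.shape) < config.genotype_missing_rate
        vals = dosages.to_numpy()
        vals[mask] = np.nan
        dosages = pd.DataFrame(vals, index=dosages.index,
                               columns=dosages.columns)

    cohort = TrioCohort(dosages=dosages, snp_table=snp_table,
                        pedigree=pedigree, config=config)
    cohort.validate()
    return cohort


# ---------------------------------------------------------------------------
# phenotypes

def _oriented_maternal_grs(cohort: TrioCohort, ids: np.ndarray) -> np.ndarray:
    """Sum of counted-allele dosages over maternal-effect score SNPs."""
    snp = cohort.snp_table
    cols = snp.loc[snp.effect_class.isin(["maternal_only", "both"]),
                   "snp_id"].to_numpy()
    g = cohort.dosages.loc[ids, cols].to_numpy()
    # missing dosages enter at their SNP mean so the latent path is defined
    col_mean = np.nanmean(g, axis=0)
    g = np.where(np.isnan(g), col_mean, g)
    return g.sum(axis=1)


def simulate_phenotypes(cohort: TrioCohort, config: SimConfig | None = None
                        ) -> TrioCohort:
    """Fill in latent outcomes and raw phenotype measurements.

    The latent intrauterine factor is U = gamma*z(GRS_m) + e with unit
    variance; standardized birthweight is lambda1*U plus direct fetal
    effects plus a disturbance, and the standardized outcome is lambda2*U
    plus fetal pleiotropy plus a background-SNP polygenic component plus a
    disturbance, the two disturbances having covariance theta.  Raw
    measurements (three BP readings, unadjusted medicated readings,
    biochemistry, registry fields) are then emitted around the latent
    values.  Uses a fresh generator seeded at ``config.seed + 1`` so the
    draw order is independent of the genotype stage.
    """
    config = config or cohort.config
    if config is None:
        raise ConfigurationError("no configuration available")
    config.validate()
    rng = np.random.default_rng(config.seed + 1)
    ped = cohort.pedigree
    snp = cohort.snp_table

    off = ped[ped.role == "offspring"]
    ids_o = off["individual_id"].to_numpy()
    n_o = len(ids_o)

    # latent factor
    mother_of_fam = (ped[ped.role == "mother"]
                     .set_index("family_id")["individual_id"])
    grs_m_raw = _oriented_maternal_grs(
        cohort, mother_of_fam.loc[off["family_id"]].to_numpy())
    z_m = (grs_m_raw - grs_m_raw.mean()) / grs_m_raw.std(ddof=0)
    u = config.gamma * z_m + np.sqrt(1 - config.gamma ** 2) * rng.standard_normal(n_o)

    # direct fetal contributions (centered genotypes)
    g_o = cohort.dosages.loc[ids_o].to_numpy()
    g_o = np.where(np.isnan(g_o), 2 * snp["freq"].to_numpy(), g_o)
    centered = g_o - 2 * snp["freq"].to_numpy()
    fet_bw = centered @ snp["fetal_bw_effect"].to_numpy()
    fet_out = centered @ snp["fetal_pleiotropy"].to_numpy()

    # polygenic outcome component from background SNPs
    bg = (snp.effect_class == "background").to_numpy()
    poly = np.zeros(n_o)
    if bg.any() and config.polygenic_h2 > 0:
        p_bg = snp.loc[bg, "freq"].to_numpy()
        w = centered[:, bg] / np.sqrt(2 * p_bg * (1 - p_bg))
        effects = rng.normal(0.0, np.sqrt(config.polygenic_h2 / bg.sum()),
                             size=int(bg.sum()))
        poly = w @ effects

    v_bw, v_out = config.residual_variances()
    cov = np.array([[v_bw, config.theta], [config.theta, v_out]])
    eps = rng.multivariate_normal([0.0, 0.0], cov, size=n_o,
                                  method="cholesky") if v_bw > 0 and v_out > 0 \
        else np.zeros((n_o, 2))
    bw_std = config.lambda1 * u + fet_bw + eps[:, 0]
    out_std = config.lambda2 * u + fet_out + poly + eps[:, 1]

    # parents get independent outcome liabilities (their own in-utero
    # history is outside the model)
    n_all = len(ped)
    liab = np.zeros(n_all)
    is_off = (ped.role == "offspring").to_numpy()
    liab[is_off] = out_std
    liab[~is_off] = rng.standard_normal(int((~is_off).sum()))

    occasion = np.where(rng.random(n_all) < config.p_occasion3, 3, 2)
    survey = np.where(occasion == 3, SURVEY_YEARS[3], SURVEY_YEARS[2])
    age = survey - ped["birth_year"].to_numpy() + rng.random(n_all)

    # blood pressure: three readings; medicated individuals' stored
    # readings are the treated ones (adjustment is the pipeline's job)
    med = (rng.random(n_all) < config.bp_med_prevalence).astype(int)
    sbp_latent = 125 + 15 * liab
    dbp_latent = 75 + 10 * (0.6 * liab + 0.8 * rng.standard_normal(n_all))
    sbp_base = sbp_latent - 15 * med
    dbp_base = dbp_latent - 10 * med
    sd_s, sd_d = config.sbp_reading_sd, config.dbp_reading_sd
    sbp = np.column_stack([
        sbp_base + 2.5 + rng.normal(0, sd_s, n_all),
        sbp_base + rng.normal(0, sd_s, n_all),
        sbp_base + rng.normal(0, sd_s, n_all)])
    dbp = np.column_stack([
        dbp_base + 2.0 + rng.normal(0, sd_d, n_all),
        dbp_base + rng.normal(0, sd_d, n_all),
        dbp_base + rng.normal(0, sd_d, n_all)])
    two_only = rng.random(n_all) >= config.p_three_bp_readings
    sbp[two_only, 2] = np.nan
    dbp[two_only, 2] = np.nan

    glucose = np.exp(rng.normal(1.61, 0.18, n_all) + 0.10 * liab)
    tc = 5.3 + 0.30 * liab + rng.normal(0, 1.0, n_all)
    hdl = np.clip(1.33 - 0.08 * liab + rng.normal(0, 0.30, n_all), 0.4, None)
    tg = np.exp(rng.normal(0.18, 0.45, n_all) + 0.15 * liab)
    is_male = (ped["sex"] == "M").to_numpy()
    height = np.where(is_male, rng.normal(1.79, 0.07, n_all),
                      rng.normal(1.66, 0.065, n_all))
    bmi = np.exp(rng.normal(3.26, 0.15, n_all) + 0.08 * liab)
    weight = bmi * height ** 2

    for arr in (glucose, tc, hdl, tg):
        miss = rng.random(n_all) < config.biochem_missing_rate
        arr[miss] = np.nan

    # birth registry fields, offspring in the registry era only
    bw_g = np.full(n_all, np.nan)
    gest = np.full(n_all, np.nan)
    csec = np.full(n_all, np.nan)
    multi = np.full(n_all, np.nan)
    malf = np.full(n_all, np.nan)
    in_reg = is_off & (ped["birth_year"].to_numpy() >= 1967)
    n_reg_draws = int(is_off.sum())
    bw_all = np.round(3500 + 520 * bw_std)
    gest_all = np.round(rng.normal(config.gestation_mean, config.gestation_sd,
                                   n_reg_draws))
    csec_all = (rng.random(n_reg_draws) < config.csection_induced_rate)
    multi_all = (rng.random(n_reg_draws) < config.multiple_birth_rate)
    malf_all = (rng.random(n_reg_draws) < config.malformation_rate)
    reg_of_off = in_reg[is_off]
    bw_g[in_reg] = bw_all[reg_of_off]
    gest[in_reg] = gest_all[reg_of_off]
    csec[in_reg] = csec_all[reg_of_off].astype(float)
    multi[in_reg] = multi_all[reg_of_off].astype(float)
    malf[in_reg] = malf_all[reg_of_off].astype(float)

    phen = pd.DataFrame({
        "sbp1": sbp[:, 0], "sbp2": sbp[:, 1], "sbp3": sbp[:, 2],
        "dbp1": dbp[:, 0], "dbp2": dbp[:, 1], "dbp3": dbp[:, 2],
        "bp_med": med,
        "glucose": glucose, "tc": tc, "hdl": hdl, "tg": tg,
        "weight_kg": weight, "height_m": height,
        "birthweight_g": bw_g, "gestation_days": gest,
        "csection_or_induced": csec, "multiple_birth": multi,
        "malformation": malf,
        "age": age, "sex": ped["sex"].to_numpy(), "occasion": occasion,
    }, index=pd.Index(ped["individual_id"], name="individual_id"))

    latents = pd.DataFrame(
        {"u": u, "bw_std": bw_std, "outcome_std": out_std},
        index=pd.Index(ids_o, name="individual_id"))
    return replace(cohort, phenotypes=phen, config=config, latents=latents)


def simulate_cohort(config: SimConfig) -> TrioCohort:
    """Genotypes and phenotypes in one call."""
    return simulate_phenotypes(simulate_genotypes(config), config)


# ---------------------------------------------------------------------------
# score definitions

def score_definitions(cohort: TrioCohort) -> dict[str, pd.DataFrame]:
    """The three nested birthweight score panels for a simulated cohort.

    Returns score tables (columns snp_id, bw_increasing_allele) for
    ``all_autosomal`` (every score-class SNP), ``maternal_effect``
    (maternal_only + both) and ``maternal_only``.  The birthweight-
    increasing allele is the counted allele when the product of the
    GRS-to-factor and factor-to-birthweight paths is positive, and the
    other allele when it is negative.
    """
    config = cohort.config or SimConfig()
    snp = cohort.snp_table
    increasing_is_counted = config.gamma * config.lambda1 >= 0

    def _table(classes: list[str]) -> pd.DataFrame:
        sub = snp[snp.effect_class.isin(classes)]
        allele = sub["counted_allele"] if increasing_is_counted \
            else sub["other_allele"]
        return pd.DataFrame({
            "snp_id": sub["snp_id"].to_numpy(),
            "bw_increasing_allele": allele.to_numpy(),
        })

    return {
        "all_autosomal": _table(["maternal_only", "both", "fetal_only"]),
        "maternal_effect": _table(["maternal_only", "both"]),
        "maternal_only": _table(["maternal_only"]),
    }
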