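"""Phenotype preparation and the conditional GRS analysis families.

Preparation follows population-survey convention: systolic/diastolic blood
pressure is the mean of the second and third readings (second alone when
only two were taken), with +15/+10 mmHg added for self-reported
antihypertensive users; LDL is derived by the Friedewald formula; glucose,
triglycerides and BMI are natural-log transformed; every analysis variable
is trimmed once at 4 SDs from its (post-transform) mean.  Birth-registry
records are screened for multiple births, malformations, induced or
C-section deliveries, birthweight under 1000 g and gestation under 258
days before birthweight is used as a predictor.

Three analysis families are fitted through the eigen-rotated FIML mixed
model: phenotypic birthweight models (outcome ~ birthweight +
birthweight^2 + covariates), conditional GRS models (outcome ~ exposure
GRS + conditioning GRS + covariates, the exposure tested by likelihood
ratio), and the same conditional models within age strata [20,40) and
[40,60).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .lmm import LMMFit, LRTResult, fit_fiml, lrt
from .scores import RelatednessMatrix, eigendecompose

__all__ = [
    "AnalysisSpec", "AssociationResult",
    "prepare_bp", "derive_ldl", "transform_and_trim",
    "birthweight_exclusions", "prepare_battery",
    "fit_phenotypic_bw_model", "fit_conditional_grs", "stratify_by_age",
    "results_table",
]

#: analysis variables and whether they are log-transformed before trimming
LOG_FIRST = {"glucose": True, "tg": True, "bmi": True,
             "sbp": False, "dbp": False, "tc": False, "ldl": False,
             "hdl": False}

SBP_MED_ADJ = 15.0
DBP_MED_ADJ = 10.0
FRIEDEWALD_DIVISOR = 2.2
TRIM_SD = 4.0


@dataclass
class AnalysisSpec:
    """One conditional GRS analysis: what is tested, conditioned and
    adjusted for, and in which age stratum."""

    outcome: str
    exposure: str          # maternal | paternal | offspring
    conditioning: str      # maternal | paternal | offspring
    score_set: str = "all_autosomal"
    covariates: tuple[str, ...] = ("age", "sex", "occasion")
    stratum: str = "all"   # all | 20-40 | 40-60

    def __post_init__(self):
        if self.exposure == self.conditioning:
            raise ValueError("exposure and conditioning scores must differ")


@dataclass
class AssociationResult:
    spec: AnalysisSpec
    effect: float
    se: float
    p: float
    n: int
    lrt_stat: float
    full_fit: LMMFit | None = field(default=None, repr=False)


# ---------------------------------------------------------------------------
# phenotype preparation

def prepare_bp(readings: np.ndarray, med_flag: np.ndarray,
               which: str = "sbp") -> np.ndarray:
    """Average the 2nd and 3rd readings (2nd alone when the 3rd is absent)
    and add the medication adjustment (+15 SBP / +10 DBP) afterwards.

    ``readings`` is (n, 3); a missing first or second reading makes the
    value missing.
    """
    readings = np.asarray(readings, dtype=float)
    if readings.ndim != 2 or readings.shape[1] != 3:
        raise ValueError("expected an (n, 3) array of readings")
    r2, r3 = readings[:, 1], readings[:, 2]
    value = np.where(np.isnan(r3), r2, (r2 + r3) / 2.0)
    # fewer than two readings -> missing
    value = np.where(np.isnan(readings[:, 0]) | np.isnan(r2), np.nan, value)
    adj = SBP_MED_ADJ if which == "sbp" else DBP_MED_ADJ
    med = np.nan_to_num(np.asarray(med_flag, dtype=float)) > 0
    return value + adj * med


def derive_ldl(tc: np.ndarray, hdl: np.ndarray, tg: np.ndarray) -> np.ndarray:
    """Friedewald LDL (mmol/L): TC - HDL - TG/2.2; missing if any input is."""
    tc = np.asarray(tc, dtype=float)
    hdl = np.asarray(hdl, dtype=float)
    tg = np.asarray(tg, dtype=float)
    return tc - hdl - tg / FRIEDEWALD_DIVISOR


def transform_and_trim(values: np.ndarray, variable: str,
                       min_n: int = 10) -> np.ndarray:
    """Log-transform (for glucose/TG/BMI) then set values strictly more
    than 4 SD from the post-transform mean to missing.  One pass, never
    iterated."""
    if variable not in LOG_FIRST:
        raise ValueError(f"unknown analysis variable {variable!r}")
    x = np.asarray(values, dtype=float).copy()
    if LOG_FIRST[variable]:
        with np.errstate(divide="ignore", invalid="ignore"):
            x = np.where(x > 0, np.log(x), np.nan)
    ok = ~np.isnan(x)
    if ok.sum() < min_n:
        warnings.warn(f"{variable}: fewer than {min_n} values, trim skipped")
        return x
    mu, sd = x[ok].mean(), x[ok].std(ddof=0)
    if sd > 0:
        x[np.abs(x - mu) > TRIM_SD * sd] = np.nan
    return x


def birthweight_exclusions(phen: pd.DataFrame) -> pd.Series:
    """Registry eligibility for birthweight analyses.

    Excluded: multiple birth, congenital malformation, induced or
    C-section delivery, birthweight < 1000 g, gestation < 258 days.
    Missing flags count as eligible (logged); missing birthweight makes
    the row ineligible for birthweight models anyway.
    """
    def _flag(col):
        v = phen.get(col)
        if v is None:
            return pd.Series(False, index=phen.index)
        return v.fillna(0).astype(float) > 0

    excluded = (_flag("multiple_birth") | _flag("malformation")
                | _flag("csection_or_induced")
                | (phen["birthweight_g"] < 1000)
                | (phen["gestation_days"] < 258))
    flag_cols = [c for c in ("multiple_birth", "malformation",
                             "csection_or_induced") if c in phen.columns]
    has_bw = phen["birthweight_g"].notna()
    if flag_cols:
        n_missing_flags = int((phen[flag_cols].isna().any(axis=1)
                               & has_bw).sum())
        if n_missing_flags:
            warnings.warn(f"{n_missing_flags} rows with missing registry "
                          "flags treated as eligible")
    return ~excluded.fillna(False) & has_bw


def prepare_battery(phen: pd.DataFrame) -> pd.DataFrame:
    """Raw measurement table -> cleaned analysis battery.

    Returns one row per individual with columns sbp, dbp, glucose (log),
    tc, ldl, hdl, tg (log), bmi (log), age, sex (0/1 male), occasion,
    birthweight_kg and bw_eligible.
    """
    out = pd.DataFrame(index=phen.index)
    sbp_read = phen[["sbp1", "sbp2", "sbp3"]].to_numpy()
    dbp_read = phen[["dbp1", "dbp2", "dbp3"]].to_numpy()
    med = phen["bp_med"].to_numpy()
    out["sbp"] = prepare_bp(sbp_read, med, "sbp")
    out["dbp"] = prepare_bp(dbp_read, med, "dbp")
    out["glucose"] = phen["glucose"]
    out["tc"] = phen["tc"]
    out["hdl"] = phen["hdl"]
    out["tg"] = phen["tg"]
    out["ldl"] = derive_ldl(phen["tc"], phen["hdl"], phen["tg"])
    out["bmi"] = phen["weight_kg"] / phen["height_m"] ** 2
    for var in ["sbp", "dbp", "glucose", "tc", "ldl", "hdl", "tg", "bmi"]:
        out[var] = transform_and_trim(out[var].to_numpy(), var)
    out["age"] = phen["age"]
    out["sex"] = (phen["sex"] == "M").astype(float)
    out["occasion"] = phen["occasion"].astype(float)
    out["birthweight_kg"] = phen["birthweight_g"] / 1000.0
    out["bw_eligible"] = birthweight_exclusions(phen)
    return out


def stratify_by_age(battery: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Half-open age strata [20, 40) and [40, 60); 60+ not analysed."""
    age = battery["age"]
    strata = {"20-40": battery[(age >= 20) & (age < 40)],
              "40-60": battery[(age >= 40) & (age < 60)]}
    for name in list(strata):
        if strata[name].empty:
            warnings.warn(f"age stratum {name} is empty; skipped")
            del strata[name]
    return strata


# ---------------------------------------------------------------------------
# model fitting

def _analysis_frame(battery: pd.DataFrame, pairs: pd.DataFrame,
                    outcome: str, extra: dict[str, pd.Series],
                    covariates: tuple[str, ...],
                    stratum: str) -> pd.DataFrame:
    """Assemble one row per parent-offspring pair, listwise complete."""
    df = pd.DataFrame(index=pd.Index(pairs["offspring_id"].to_numpy(),
                                     name="offspring_id"))
    off = battery.loc[df.index]
    df["y"] = off[outcome].to_numpy()
    for name, series in extra.items():
        df[name] = series.to_numpy()
    for cov in covariates:
        df[cov] = off[cov].to_numpy()
    if stratum == "20-40":
        df = df[(df["age"] >= 20) & (df["age"] < 40)]
    elif stratum == "40-60":
        df = df[(df["age"] >= 40) & (df["age"] < 60)]
    elif stratum != "all":
        raise ValueError(f"unknown stratum {stratum!r}")
    return df.dropna()


def _fit_with_grm(df: pd.DataFrame, xcols: list[str],
                  grm: RelatednessMatrix | None
                  ) -> tuple[LMMFit, np.ndarray, np.ndarray | None,
                             np.ndarray | None]:
    """Fit the full model, returning the fit plus the design and the
    eigendecomposition used (None, None under independence)."""
    y = df["y"].to_numpy()
    X = df[xcols].to_numpy()
    if grm is None:
        fit = fit_fiml(y, X)
        return fit, X, None, None
    sub = grm.subset(list(df.index))
    sub = eigendecompose(sub)
    fit = fit_fiml(y, X, eigenvalues=sub.eigenvalues,
                   eigenvectors=sub.eigenvectors)
    return fit, X, sub.eigenvalues, sub.eigenvectors


def fit_conditional_grs(battery: pd.DataFrame, pairs: pd.DataFrame,
                        grs: dict[str, pd.Series],
                        spec: AnalysisSpec,
                        grm: RelatednessMatrix | None = None,
                        max_grs_missing: float = 0.20) -> AssociationResult:
    """Conditional GRS association for one outcome and configuration.

    ``pairs`` holds one row per parent-offspring pair (columns parent_id,
    offspring_id); ``grs`` maps 'maternal'/'paternal'/'offspring' to
    per-pair score Series aligned with ``pairs`` rows.  The outcome is
    z-scored within the analysis sample; scores stay on the allele-count
    scale, so effects are standardized-outcome units per allele.  The
    exposure term is tested by likelihood ratio against the sub-model
    with that term removed.
    """
    for role in (spec.exposure, spec.conditioning):
        if role not in grs:
            raise ValueError(f"no GRS supplied for role {role!r}")
        frac_missing = float(np.mean(np.isnan(
            np.asarray(grs[role], dtype=float))))
        if frac_missing > max_grs_missing:
            raise ValueError(
                f"{role} GRS missing for {frac_missing:.0%} of pairs "
                f"(> {max_grs_missing:.0%}); refusing to fit")

    extra = {"g_exp": pd.Series(np.asarray(grs[spec.exposure], dtype=float)),
             "g_cond": pd.Series(np.asarray(grs[spec.conditioning],
                                            dtype=float))}
    df = _analysis_frame(battery, pairs, spec.outcome, extra,
                         spec.covariates, spec.stratum)
    if len(df) < 10:
        raise ValueError(f"only {len(df)} complete rows; refusing to fit")
    df = df.copy()
    df["y"] = (df["y"] - df["y"].mean()) / df["y"].std(ddof=0)

    xcols = ["g_exp", "g_cond", *spec.covariates]
    full, X, d, U = _fit_with_grm(df, xcols, grm)
    y = df["y"].to_numpy()
    X_sub = df[["g_cond", *spec.covariates]].to_numpy()
    sub = fit_fiml(y, X_sub, eigenvalues=d, eigenvectors=U)
    test = lrt(full, sub, df=1)
    return AssociationResult(spec=spec, effect=float(full.beta[1]),
                             se=float(full.se[1]), p=test.p, n=len(df),
                             lrt_stat=test.stat, full_fit=full)


def fit_phenotypic_bw_model(battery: pd.DataFrame, pairs: pd.DataFrame,
                            outcome: str,
                            grm: RelatednessMatrix | None = None,
                            covariates: tuple[str, ...] = ("age", "sex",
                                                           "occasion"),
                            min_rows: int = 100) -> pd.DataFrame:
    """Outcome ~ birthweight + birthweight^2 + covariates for registry-
    eligible offspring; linear and quadratic terms tested by LRT."""
    eligible = battery["bw_eligible"].reindex(
        pairs["offspring_id"]).fillna(False).to_numpy()
    pairs = pairs[eligible]
    bw = battery["birthweight_kg"].reindex(pairs["offspring_id"])
    extra = {"bw": bw, "bw2": bw ** 2}
    df = _analysis_frame(battery, pairs, outcome, extra, covariates, "all")
    if len(df) < min_rows:
        raise ValueError(f"only {len(df)} eligible rows (need {min_rows})")
    df = df.copy()
    df["y"] = (df["y"] - df["y"].mean()) / df["y"].std(ddof=0)

    xcols = ["bw", "bw2", *covariates]
    full, X, d, U = _fit_with_grm(df, xcols, grm)
    y = df["y"].to_numpy()
    rows = []
    for k, term in enumerate(["bw", "bw2"]):
        drop = [c for c in xcols if c != term]
        sub = fit_fiml(y, df[drop].to_numpy(), eigenvalues=d, eigenvectors=U)
        test = lrt(full, sub, df=1)
        rows.append({"outcome": outcome, "term": term,
                     "effect": float(full.beta[1 + k]),
                     "se": float(full.se[1 + k]), "p": test.p,
                     "n": len(df)})
    return pd.DataFrame(rows)


def results_table(results: list[AssociationResult],
                  path: str | None = None) -> pd.DataFrame:
    """Flatten association results (one row each) and optionally write TSV
    with columns outcome, score_set, exposure, stratum, effect, se, p, n."""
    rows = [{
        "outcome": r.spec.outcome, "score_set": r.spec.score_set,
        "exposure": r.spec.exposure, "conditioning": r.spec.conditioning,
        "stratum": r.spec.stratum, "effect": r.effect, "se": r.se,
        "p": r.p, "n": r.n,
    } for r in results]
    table = pd.DataFrame(rows)
    if path is not None:
        table.to_csv(path, sep="\t", index=False)
    return table
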