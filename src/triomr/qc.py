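"""Sample/variant QC, KING-robust kinship and analysis-pair construction.

Parent-offspring pairs are found by genotype-based kinship inference
rather than reported pedigrees: the KING-robust within/between-family
estimator is computed from hard-called genotypes, pairs are classified
into relationship degrees by the estimator's recommended kinship
intervals, first-degree pairs are split into parent-offspring versus
full-sibling by the fraction of opposite-homozygote SNPs (IBS0, which is
essentially zero for parent-offspring pairs), and putative pairs whose
birth years differ by 15 years or fewer are discarded as implausible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .simulate import TrioCohort

__all__ = [
    "QCReport", "KinshipResult", "AnalysisPairs",
    "sample_qc", "variant_qc", "king_kinship", "classify_relationship",
    "build_pairs",
]

# KING's recommended kinship intervals, spaced by powers of 2^(-1/2):
# duplicate > 1/2^1.5, first degree > 1/2^2.5, second > 1/2^3.5,
# third > 1/2^4.5
DEGREE_CUTOFFS = (0.3536, 0.1768, 0.0884, 0.0442)
#: IBS0 fraction below which a first-degree pair is called parent-offspring
PO_IBS0_CUTOFF = 0.005


@dataclass
class QCReport:
    """Per-filter removal counts and the thresholds that produced them."""

    removed: dict[str, int] = field(default_factory=dict)
    thresholds: dict[str, float] = field(default_factory=dict)
    notes: list[str] = field(default_factory=list)
    n_before: int = 0
    n_after: int = 0


@dataclass
class KinshipResult:
    id1: str
    id2: str
    kinship: float
    ibs0_fraction: float
    n_overlap: int
    degree: str | None = None
    estimable: bool = True


@dataclass
class AnalysisPairs:
    """Mother-offspring and father-offspring analysis pairs.

    ``table`` has columns parent_id, offspring_id, parent_role, gap_years.
    """

    table: pd.DataFrame

    def for_role(self, parent_role: str) -> pd.DataFrame:
        return self.table[self.table.parent_role == parent_role]

    @property
    def n_mother_offspring(self) -> int:
        return int((self.table.parent_role == "mother").sum())

    @property
    def n_father_offspring(self) -> int:
        return int((self.table.parent_role == "father").sum())


# ---------------------------------------------------------------------------
# sample / variant QC

def _heterozygosity(dosages: pd.DataFrame) -> np.ndarray:
    """Fraction of hard-called genotypes equal to 1, per individual."""
    g = np.round(dosages.to_numpy())
    valid = ~np.isnan(g)
    with np.errstate(invalid="ignore"):
        return np.where(valid.sum(1) > 0,
                        np.nansum(g == 1, axis=1) / valid.sum(1), np.nan)


def sample_qc(cohort: TrioCohort, het_sd: float = 5.0,
              sex_mismatch_field: str = "sex_mismatch"
              ) -> tuple[TrioCohort, QCReport]:
    """Remove heterozygosity outliers (beyond ``het_sd`` SDs of the mean)
    and individuals flagged sex-mismatched in the pedigree metadata."""
    report = QCReport(n_before=cohort.n_individuals,
                      thresholds={"het_sd": het_sd})
    het = _heterozygosity(cohort.dosages)
    mu, sd = np.nanmean(het), np.nanstd(het, ddof=0)
    if sd == 0:
        het_out = np.zeros(len(het), dtype=bool)
    else:
        het_out = np.abs(het - mu) > het_sd * sd
    report.removed["heterozygosity"] = int(het_out.sum())

    if sex_mismatch_field in cohort.pedigree.columns:
        flagged = cohort.pedigree.set_index("individual_id")[
            sex_mismatch_field].reindex(cohort.dosages.index).fillna(False)
        sex_out = flagged.to_numpy().astype(bool)
    else:
        sex_out = np.zeros(len(het), dtype=bool)
        report.notes.append("sex-mismatch check skipped: no metadata field")
    report.removed["sex_mismatch"] = int(sex_out.sum())

    keep_ids = cohort.dosages.index[~(het_out | sex_out)]
    if len(keep_ids) == 0:
        raise ValueError("sample QC removed every individual")
    filtered = replace(
        cohort,
        dosages=cohort.dosages.loc[keep_ids],
        pedigree=cohort.pedigree[
            cohort.pedigree.individual_id.isin(keep_ids)].reset_index(drop=True),
        phenotypes=(cohort.phenotypes.loc[
            cohort.phenotypes.index.intersection(keep_ids)]
            if cohort.phenotypes is not None else None),
    )
    report.n_after = filtered.n_individuals
    return filtered, report


def variant_qc(cohort: TrioCohort, maf_min: float = 0.005,
               miss_max: float = 0.05) -> tuple[TrioCohort, QCReport]:
    """Drop SNPs with minor allele frequency < ``maf_min`` or missing
    fraction strictly greater than ``miss_max`` (both bounds as printed:
    MAF < 0.005 removes, exactly 5% missing is retained)."""
    report = QCReport(n_before=cohort.dosages.shape[1],
                      thresholds={"maf_min": maf_min, "miss_max": miss_max})
    g = cohort.dosages.to_numpy()
    miss = np.isnan(g).mean(axis=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        freq = np.nanmean(g, axis=0) / 2.0
    maf = np.minimum(freq, 1 - freq)
    maf = np.where(np.isnan(maf), 0.0, maf)
    low_maf = maf < maf_min
    high_miss = miss > miss_max
    report.removed["maf"] = int(low_maf.sum())
    report.removed["missingness"] = int(high_miss.sum())
    keep = ~(low_maf | high_miss)
    if not keep.any():
        raise ValueError("variant QC removed every SNP")
    filtered = replace(
        cohort,
        dosages=cohort.dosages.loc[:, keep],
        snp_table=cohort.snp_table.loc[keep].reset_index(drop=True),
    )
    report.n_after = filtered.dosages.shape[1]
    return filtered, report


# ---------------------------------------------------------------------------
# kinship

def king_kinship(dosages: pd.DataFrame,
                 pairs: list[tuple[str, str]] | None = None,
                 min_overlap: int = 100) -> list[KinshipResult]:
    """KING-robust kinship from hard-called genotypes.

    kinship = (N_het,het - 2*N_opposite_hom) / (N_het(i) + N_het(j)),
    heterozygote counts taken over the SNPs non-missing in both members
    (the symmetric-denominator form, so the estimate does not depend on
    pair order).  ``ibs0_fraction`` is the fraction of overlapping SNPs at
    which the two individuals are opposite homozygotes.  With ``pairs``
    None, every unordered pair is evaluated via matrix products.
    """
    g = np.round(dosages.to_numpy())
    ids = list(dosages.index)
    het = (g == 1)
    aa = (g == 2)
    oo = (g == 0)
    valid = ~np.isnan(g)
    hetv = np.where(valid, het, False).astype(np.float64)
    aav = np.where(valid, aa, False).astype(np.float64)
    oov = np.where(valid, oo, False).astype(np.float64)
    validf = valid.astype(np.float64)

    def _one(i: int, j: int) -> KinshipResult:
        both = valid[i] & valid[j]
        n_overlap = int(both.sum())
        if n_overlap < min_overlap:
            return KinshipResult(ids[i], ids[j], np.nan, np.nan, n_overlap,
                                 estimable=False)
        n_hh = int((het[i] & het[j] & both).sum())
        n_opp = int(((aa[i] & oo[j]) | (oo[i] & aa[j])).sum())
        n_het_i = int((het[i] & both).sum())
        n_het_j = int((het[j] & both).sum())
        denom = n_het_i + n_het_j
        phi = (n_hh - 2 * n_opp) / denom if denom > 0 else np.nan
        return KinshipResult(ids[i], ids[j], phi, n_opp / n_overlap,
                             n_overlap)

    if pairs is not None:
        index = {s: k for k, s in enumerate(ids)}
        return [_one(index[a], index[b]) for a, b in pairs]

    # all pairs at once
    n_hh = hetv @ hetv.T
    n_opp = aav @ oov.T + oov @ aav.T
    n_het_in_overlap = hetv @ validf.T        # het(i) over SNPs valid in j
    n_overlap = validf @ validf.T
    results = []
    n = len(ids)
    for i in range(n):
        for j in range(i + 1, n):
            ov = int(n_overlap[i, j])
            if ov < min_overlap:
                results.append(KinshipResult(ids[i], ids[j], np.nan, np.nan,
                                             ov, estimable=False))
                continue
            denom = n_het_in_overlap[i, j] + n_het_in_overlap[j, i]
            phi = ((n_hh[i, j] - 2 * n_opp[i, j]) / denom
                   if denom > 0 else np.nan)
            results.append(KinshipResult(ids[i], ids[j], phi,
                                         n_opp[i, j] / ov, ov))
    return results


def classify_relationship(k: KinshipResult) -> str:
    """Assign a relationship degree from the kinship estimate; split
    first-degree pairs into parent-offspring vs full-sibling by IBS0."""
    if not k.estimable or np.isnan(k.kinship):
        return "unestimable"
    phi = k.kinship
    if phi > DEGREE_CUTOFFS[0]:
        degree = "duplicate"
    elif phi > DEGREE_CUTOFFS[1]:
        degree = ("parent_offspring" if k.ibs0_fraction < PO_IBS0_CUTOFF
                  else "full_sibling")
    elif phi > DEGREE_CUTOFFS[2]:
        degree = "second"
    elif phi > DEGREE_CUTOFFS[3]:
        degree = "third"
    else:
        degree = "unrelated"
    k.degree = degree
    return degree


# ---------------------------------------------------------------------------
# analysis pairs

def build_pairs(relationships: list[KinshipResult], pedigree: pd.DataFrame,
                max_gap_excl: int = 15) -> AnalysisPairs:
    """Turn classified parent-offspring relationships into analysis pairs.

    The older member is assigned the parent role; pairs whose birth years
    differ by ``max_gap_excl`` years or fewer (or tie) are removed; the
    parent's sex determines the mother- vs father-offspring set.  A parent
    may appear in many pairs (one row per offspring).
    """
    meta = pedigree.set_index("individual_id")
    rows = []
    for k in relationships:
        degree = k.degree if k.degree is not None else classify_relationship(k)
        if degree != "parent_offspring":
            continue
        try:
            by1 = meta.at[k.id1, "birth_year"]
            by2 = meta.at[k.id2, "birth_year"]
        except KeyError:
            warnings.warn(f"pair ({k.id1}, {k.id2}) skipped: missing "
                          "birth year")
            continue
        if pd.isna(by1) or pd.isna(by2):
            warnings.warn(f"pair ({k.id1}, {k.id2}) skipped: missing "
                          "birth year")
            continue
        gap = abs(int(by1) - int(by2))
        if gap <= max_gap_excl:   # includes the birth-year tie
            continue
        parent, child = (k.id1, k.id2) if by1 < by2 else (k.id2, k.id1)
        sex = meta.at[parent, "sex"]
        role = "mother" if sex == "F" else "father"
        rows.append((parent, child, role, gap))
    table = pd.DataFrame(rows, columns=["parent_id", "offspring_id",
                                        "parent_role", "gap_years"])
    table = table.drop_duplicates(["offspring_id", "parent_role"])
    return AnalysisPairs(table=table.reset_index(drop=True))
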