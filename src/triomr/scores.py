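"""Unweighted birthweight genetic risk scores and the genetic relationship
matrix (GRM).

Scores are simple sums, over the SNPs of a panel, of the expected number of
birthweight-increasing alleles carried (real-valued with imputed dosages).
Scores are deliberately unweighted: the per-allele effect on growth
restriction is unknown, so weighting by observed birthweight effects would
impose the wrong metric.

The GRM uses the standardized-genotype product formula
A_jk = (1/m) * sum_i (x_ij - 2 p_i)(x_ik - 2 p_i) / (2 p_i (1 - p_i)),
computed after excluding the score SNPs and a 1 Mb window around them so
that association signal carried by the scores is not absorbed into the
random-effects structure.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ScoreDefinition", "GRSVector", "RelatednessMatrix",
    "build_grs", "exclusion_mask", "build_grm", "eigendecompose",
]


@dataclass
class ScoreDefinition:
    """A named panel of (snp_id, birthweight-increasing allele) entries."""

    name: str
    entries: pd.DataFrame  # columns: snp_id, bw_increasing_allele

    @classmethod
    def from_table(cls, name: str, table: pd.DataFrame) -> "ScoreDefinition":
        if table["snp_id"].duplicated().any():
            raise ValueError("score definition contains duplicate snp_ids")
        return cls(name=name, entries=table.reset_index(drop=True))


@dataclass
class GRSVector:
    name: str
    scores: pd.Series           # individual_id -> score, NaN if unscoreable
    n_snps_used: int
    dropped_snps: list[str] = field(default_factory=list)


@dataclass
class RelatednessMatrix:
    """Symmetric relatedness matrix with optional eigendecomposition."""

    A: np.ndarray
    sample_ids: list[str]
    m: int
    eigenvalues: np.ndarray | None = None
    eigenvectors: np.ndarray | None = None

    def subset(self, ids: list[str]) -> "RelatednessMatrix":
        """Rows/columns for ``ids``; any existing decomposition is dropped
        (it is no longer valid for the submatrix)."""
        pos = {s: k for k, s in enumerate(self.sample_ids)}
        idx = np.array([pos[i] for i in ids])
        return RelatednessMatrix(A=self.A[np.ix_(idx, idx)],
                                 sample_ids=list(ids), m=self.m)

    @classmethod
    def identity(cls, ids: list[str]) -> "RelatednessMatrix":
        n = len(ids)
        return cls(A=np.eye(n), sample_ids=list(ids), m=0,
                   eigenvalues=np.ones(n), eigenvectors=np.eye(n))


def build_grs(dosages: pd.DataFrame, snp_table: pd.DataFrame,
              score: ScoreDefinition | pd.DataFrame,
              max_missing: float = 0.10, name: str | None = None
              ) -> GRSVector:
    """Sum of birthweight-increasing-allele dosages over a score panel.

    Dosages count the cohort's counted allele; entries whose increasing
    allele is the other allele contribute ``2 - dosage``.  Score entries
    that cannot be resolved against the cohort SNP table are logged and
    dropped.  A missing dosage is imputed to twice the sample frequency of
    the increasing allele; individuals missing more than ``max_missing`` of
    the panel get a missing score.
    """
    if isinstance(score, pd.DataFrame):
        score = ScoreDefinition.from_table(name or "score", score)
    meta = snp_table.set_index("snp_id")
    dropped, use_ids, flip = [], [], []
    for snp_id, allele in score.entries[
            ["snp_id", "bw_increasing_allele"]].itertuples(index=False):
        if snp_id not in meta.index or snp_id not in dosages.columns:
            dropped.append(snp_id)
            continue
        counted = meta.at[snp_id, "counted_allele"]
        other = meta.at[snp_id, "other_allele"]
        if allele == counted:
            flip.append(False)
        elif allele == other:
            flip.append(True)
        else:
            dropped.append(snp_id)
            continue
        use_ids.append(snp_id)
    if dropped:
        warnings.warn(f"score {score.name!r}: {len(dropped)} unresolvable "
                      f"entries dropped ({', '.join(dropped[:5])}...)"
                      if len(dropped) > 5 else
                      f"score {score.name!r}: unresolvable entries dropped: "
                      f"{', '.join(dropped)}")
    if not use_ids:
        raise ValueError(f"score {score.name!r}: no resolvable SNPs")

    g = dosages[use_ids].to_numpy(dtype=float)
    flip = np.asarray(flip)
    oriented = np.where(flip, 2.0 - g, g)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean_inc = np.nanmean(oriented, axis=0)   # = 2 * increasing-allele freq
    missing = np.isnan(oriented)
    oriented = np.where(missing, mean_inc, oriented)
    scores = oriented.sum(axis=1)
    too_missing = missing.mean(axis=1) > max_missing
    if too_missing.any():
        warnings.warn(f"score {score.name!r}: {int(too_missing.sum())} "
                      f"individuals missing >{max_missing:.0%} of the panel; "
                      "score set missing")
        scores[too_missing] = np.nan
    return GRSVector(name=score.name,
                     scores=pd.Series(scores, index=dosages.index),
                     n_snps_used=len(use_ids), dropped_snps=dropped)


def exclusion_mask(snp_table: pd.DataFrame, score_snp_ids: list[str],
                   window_bp: int = 1_000_000) -> pd.Series:
    """Boolean mask of SNPs farther than ``window_bp`` from every
    same-chromosome score SNP (distance <= window is excluded); score SNPs
    themselves are excluded."""
    score_set = set(score_snp_ids)
    keep = np.ones(len(snp_table), dtype=bool)
    score_rows = snp_table[snp_table.snp_id.isin(score_set)]
    by_chrom = {c: grp["position"].to_numpy()
                for c, grp in score_rows.groupby("chromosome")}
    for i, (snp_id, chrom, pos) in enumerate(zip(
            snp_table["snp_id"], snp_table["chromosome"],
            snp_table["position"])):
        if snp_id in score_set:
            keep[i] = False
            continue
        anchors = by_chrom.get(chrom)
        if anchors is not None and np.abs(anchors - pos).min() <= window_bp:
            keep[i] = False
    return pd.Series(keep, index=snp_table["snp_id"].to_numpy(),
                     name="retained")


def build_grm(dosages: pd.DataFrame, sample_ids: list[str] | None = None
              ) -> RelatednessMatrix:
    """GCTA-style standardized-product GRM over the given individuals.

    Allele frequencies are the sample frequencies of the analysis set;
    monomorphic SNPs are skipped; missing dosages enter at the SNP mean
    (zero after centering).
    """
    if sample_ids is not None:
        dosages = dosages.loc[sample_ids]
    g = dosages.to_numpy(dtype=float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        p = np.nanmean(g, axis=0) / 2.0
    poly = (p > 0) & (p < 1)
    if not poly.any():
        raise ValueError("no polymorphic SNPs left for the GRM")
    g = g[:, poly]
    p = p[poly]
    z = (g - 2 * p) / np.sqrt(2 * p * (1 - p))
    z = np.where(np.isnan(z), 0.0, z)
    m = z.shape[1]
    A = (z @ z.T) / m
    return RelatednessMatrix(A=A, sample_ids=list(dosages.index), m=m)


def eigendecompose(grm: RelatednessMatrix, tol: float = 1e-8
                   ) -> RelatednessMatrix:
    """Spectral decomposition of A: orthonormal U, eigenvalues descending,
    negatives clamped to zero (with a warning if below -``tol``)."""
    A = grm.A
    if not np.allclose(A, A.T, atol=1e-8):
        raise ValueError("relatedness matrix is not symmetric")
    d, U = np.linalg.eigh(A)
    order = np.argsort(d)[::-1]
    d, U = d[order], U[:, order]
    if (d < -tol).any():
        warnings.warn(f"clamping {int((d < -tol).sum())} negative "
                      "eigenvalues to zero")
    d = np.clip(d, 0.0, None)
    grm.eigenvalues = d
    grm.eigenvectors = U
    return grm
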