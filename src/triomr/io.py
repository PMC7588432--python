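"""Reading and writing trio cohorts.

A cohort directory contains:

* ``genotypes.vcf`` (VCF 4.2 with a DS FORMAT field) *or* ``dosages.tsv``
  (rows = individuals, columns = snp_ids, first column ``individual_id``,
  missing dosages as empty cells),
* ``snps.tsv`` — the SNP table (positions, alleles, frequencies, effects),
* ``pedigree.tsv`` — family_id, individual_id, role, sex, birth_year,
* ``phenotypes.tsv`` — one row per individual, raw measurements,
* ``scores.tsv`` — long-format score definitions
  (score_name, snp_id, bw_increasing_allele).

Writing is deterministic: the same cohort always produces byte-identical
files.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .simulate import TrioCohort

__all__ = ["write_cohort", "read_cohort", "write_score_definitions",
           "read_score_definitions"]


def _fmt_dosage(x: float) -> str:
    if np.isnan(x):
        return "."
    if x == int(x):
        return str(int(x))
    return format(x, ".6g")


def _write_vcf(cohort: TrioCohort, path: Path) -> None:
    snp = cohort.snp_table.reset_index(drop=True)
    ids = list(cohort.dosages.index)
    dose = cohort.dosages.to_numpy()
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=DS,Number=1,Type=Float,'
                 'Description="Estimated alternate allele dosage">\n')
        for c in sorted(snp["chromosome"].unique()):
            fh.write(f"##contig=<ID={c}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(ids) + "\n")
        order = snp.sort_values(["chromosome", "position"]).index
        for i in order:
            row = snp.loc[i]
            # ALT is the counted allele: DS counts copies of ALT
            vals = "\t".join(_fmt_dosage(v) for v in dose[:, i])
            fh.write(f"{row.chromosome}\t{row.position}\t{row.snp_id}\t"
                     f"{row.other_allele}\t{row.counted_allele}\t.\tPASS\t.\t"
                     f"DS\t{vals}\n")


def _read_vcf(path: Path, snp_order: list[str]) -> pd.DataFrame:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    cols: dict[str, np.ndarray] = {}
    for var in vcf:
        ds = var.format("DS")
        cols[var.ID] = np.asarray(ds, dtype=float).ravel()
    vcf.close()
    df = pd.DataFrame(cols, index=pd.Index(samples, name="individual_id"))
    return df[snp_order]


def write_cohort(cohort: TrioCohort, directory: str | Path,
                 genotype_format: str = "vcf") -> dict[str, Path]:
    """Write a cohort to ``directory``; returns the paths written."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    if genotype_format == "vcf":
        paths["genotypes"] = directory / "genotypes.vcf"
        _write_vcf(cohort, paths["genotypes"])
    elif genotype_format == "tsv":
        paths["genotypes"] = directory / "dosages.tsv"
        out = cohort.dosages.copy()
        out.index.name = "individual_id"
        out.to_csv(paths["genotypes"], sep="\t", na_rep="",
                   float_format="%.6g")
    else:
        raise ValueError(f"unknown genotype format: {genotype_format!r}")

    paths["snps"] = directory / "snps.tsv"
    cohort.snp_table.to_csv(paths["snps"], sep="\t", index=False)
    paths["pedigree"] = directory / "pedigree.tsv"
    cohort.pedigree.to_csv(paths["pedigree"], sep="\t", index=False)
    if cohort.phenotypes is not None:
        paths["phenotypes"] = directory / "phenotypes.tsv"
        cohort.phenotypes.to_csv(paths["phenotypes"], sep="\t", na_rep="")
    if cohort.config is not None:
        from .simulate import score_definitions

        paths["scores"] = write_score_definitions(
            score_definitions(cohort), directory / "scores.tsv")
    return paths


def read_cohort(directory: str | Path) -> TrioCohort:
    """Read a cohort directory written by :func:`write_cohort`."""
    directory = Path(directory)
    snp_table = pd.read_csv(directory / "snps.tsv", sep="\t")
    pedigree = pd.read_csv(directory / "pedigree.tsv", sep="\t")
    snp_order = list(snp_table["snp_id"])

    vcf_path = directory / "genotypes.vcf"
    tsv_path = directory / "dosages.tsv"
    if vcf_path.exists():
        dosages = _read_vcf(vcf_path, snp_order)
    elif tsv_path.exists():
        dosages = pd.read_csv(tsv_path, sep="\t", index_col="individual_id")
        dosages = dosages[snp_order]
    else:
        raise FileNotFoundError(
            f"no genotypes.vcf or dosages.tsv in {directory}")
    dosages = dosages.loc[pedigree["individual_id"]]
    dosages.index.name = "individual_id"

    phen_path = directory / "phenotypes.tsv"
    phenotypes = None
    if phen_path.exists():
        phenotypes = pd.read_csv(phen_path, sep="\t",
                                 index_col="individual_id")
    return TrioCohort(dosages=dosages, snp_table=snp_table,
                      pedigree=pedigree, phenotypes=phenotypes)


def write_score_definitions(scores: dict[str, pd.DataFrame],
                            path: str | Path) -> Path:
    """Write score panels as a long-format TSV."""
    frames = []
    for name, table in scores.items():
        t = table.copy()
        t.insert(0, "score_name", name)
        frames.append(t)
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)
    return Path(path)


def read_score_definitions(path: str | Path) -> dict[str, pd.DataFrame]:
    long = pd.read_csv(path, sep="\t")
    return {name: grp.drop(columns="score_name").reset_index(drop=True)
            for name, grp in long.groupby("score_name", sort=False)}
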