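"""QC filters, KING-robust kinship and analysis-pair construction."""

import numpy as np
import pandas as pd
import pytest

from triomr import (KinshipResult, TrioCohort, build_pairs,
                    classify_relationship, king_kinship, sample_qc,
                    variant_qc)


def _toy_cohort(dosages, ids=None, sex_mismatch=None):
    n, m = dosages.shape
    ids = ids or [f"I{k}" for k in range(n)]
    ped = pd.DataFrame({
        "family_id": [f"F{k}" for k in range(n)],
        "individual_id": ids,
        "role": "offspring",
        "sex": "F",
        "birth_year": 1970,
    })
    if sex_mismatch is not None:
        ped["sex_mismatch"] = sex_mismatch
    snps = pd.DataFrame({
        "snp_id": [f"s{j}" for j in range(m)],
        "chromosome": 1,
        "position": np.arange(1, m + 1) * 10_000,
        "counted_allele": "A",
        "other_allele": "G",
        "freq": 0.5,
        "effect_class": "background",
        "maternal_bw_effect": 0.0,
        "fetal_bw_effect": 0.0,
        "fetal_pleiotropy": 0.0,
    })
    dos = pd.DataFrame(np.asarray(dosages, dtype=float), index=ids,
                       columns=snps["snp_id"])
    return TrioCohort(dosages=dos, snp_table=snps, pedigree=ped)


class TestVariantQC:
    def test_boundary_rules(self, rng):
        # columns: MAF 0.004 (remove), exactly 5% missing (keep),
        # MAF 0.5 clean (keep), 6% missing (remove)
        n = 1000
        g = np.zeros((n, 4))
        g[:, 0] = rng.binomial(2, 0.004, n)
        while abs(g[:, 0].mean() / 2 - 0.004) > 0.002:   # keep MAF < 0.005
            g[:, 0] = rng.binomial(2, 0.003, n)
        g[:, 1] = rng.binomial(2, 0.5, n)
        g[:50, 1] = np.nan
        g[:, 2] = rng.binomial(2, 0.5, n)
        g[:, 3] = rng.binomial(2, 0.5, n)
        g[:60, 3] = np.nan
        cohort = _toy_cohort(g)
        filtered, report = variant_qc(cohort)
        assert list(filtered.dosages.columns) == ["s1", "s2"]
        assert report.removed["maf"] >= 1
        assert report.removed["missingness"] == 1

    def test_all_removed_raises(self):
        g = np.zeros((50, 2))       # monomorphic: MAF 0 everywhere
        with pytest.raises(ValueError):
            variant_qc(_toy_cohort(g))


class TestSampleQC:
    def test_identical_heterozygosity_removes_none(self):
        g = np.tile([0, 1, 2, 1], (20, 25))
        filtered, report = sample_qc(_toy_cohort(g[:, :100]))
        assert report.removed["heterozygosity"] == 0
        assert filtered.n_individuals == 20

    def test_outlier_removed(self, rng):
        # cohort of het ~0.3, one individual fully heterozygous
        g = rng.binomial(2, 0.2, size=(200, 400)).astype(float)
        g[0] = 1.0
        cohort = _toy_cohort(g)
        filtered, report = sample_qc(cohort)
        assert "I0" not in filtered.dosages.index
        assert report.removed["heterozygosity"] >= 1

    def test_sex_mismatch_flag_honored(self, rng):
        g = rng.binomial(2, 0.3, size=(30, 200)).astype(float)
        flags = [True] + [False] * 29
        filtered, report = sample_qc(_toy_cohort(g, sex_mismatch=flags))
        assert report.removed["sex_mismatch"] == 1
        assert "I0" not in filtered.dosages.index

    def test_missing_sex_metadata_noted(self, rng):
        g = rng.binomial(2, 0.3, size=(30, 200)).astype(float)
        _, report = sample_qc(_toy_cohort(g))
        assert any("sex" in note for note in report.notes)


class TestKinship:
    def test_duplicate_genotypes(self, rng):
        g = rng.binomial(2, 0.4, size=(1, 2000)).astype(float)
        dos = pd.DataFrame(np.vstack([g, g]), index=["a", "b"],
                           columns=[f"s{j}" for j in range(2000)])
        (res,) = king_kinship(dos)
        assert res.kinship == pytest.approx(0.5, abs=1e-12)
        assert res.ibs0_fraction == 0.0

    def test_symmetry(self, rng):
        g = rng.binomial(2, 0.4, size=(2, 2000)).astype(float)
        dos = pd.DataFrame(g, index=["a", "b"],
                           columns=[f"s{j}" for j in range(2000)])
        (fwd,) = king_kinship(dos, pairs=[("a", "b")])
        (rev,) = king_kinship(dos, pairs=[("b", "a")])
        assert fwd.kinship == rev.kinship

    def test_relationship_recovery(self, kinship_cohort):
        """Kinship means land on pedigree expectations and classification
        recovers >=99% of true first-degree pairs at 10,000 SNPs."""
        ped = kinship_cohort.pedigree
        fams = ped.family_id.unique()[:60]
        sub = ped[ped.family_id.isin(fams)]
        dos = kinship_cohort.dosages.loc[sub.individual_id]
        results = king_kinship(dos)
        truth = {}
        by_fam = sub.groupby("family_id")
        for fam, grp in by_fam:
            parents = grp[grp.role != "offspring"].individual_id.tolist()
            kids = grp[grp.role == "offspring"].individual_id.tolist()
            for p in parents:
                for k in kids:
                    truth[frozenset((p, k))] = "parent_offspring"
            for i in range(len(kids)):
                for j in range(i + 1, len(kids)):
                    truth[frozenset((kids[i], kids[j]))] = "full_sibling"

        po_k, sib_k, unrel_k = [], [], []
        hits, total = 0, 0
        for r in results:
            degree = classify_relationship(r)
            expected = truth.get(frozenset((r.id1, r.id2)))
            if expected == "parent_offspring":
                po_k.append(r.kinship)
            elif expected == "full_sibling":
                sib_k.append(r.kinship)
            elif frozenset((r.id1, r.id2)) not in truth:
                # spouses are unrelated too
                unrel_k.append(r.kinship)
            if expected is not None:
                total += 1
                hits += degree == expected
        assert abs(np.mean(po_k) - 0.25) < 0.01
        assert abs(np.mean(sib_k) - 0.25) < 0.01
        assert abs(np.mean(unrel_k)) < 0.01
        assert hits / total >= 0.99

    def test_too_few_overlapping_snps_flagged(self, rng):
        g = rng.binomial(2, 0.4, size=(2, 50)).astype(float)
        dos = pd.DataFrame(g, index=["a", "b"],
                           columns=[f"s{j}" for j in range(50)])
        (res,) = king_kinship(dos, min_overlap=100)
        assert not res.estimable
        assert classify_relationship(res) == "unestimable"


@pytest.mark.parametrize("kinship,ibs0,expected", [
    (0.52, 0.0, "duplicate"),
    (0.25, 0.0005, "parent_offspring"),
    (0.25, 0.04, "full_sibling"),
    (0.12, 0.02, "second"),
    (0.06, 0.03, "third"),
    (0.01, 0.06, "unrelated"),
])
def test_degree_classification(kinship, ibs0, expected):
    res = KinshipResult("x", "y", kinship, ibs0, 10_000)
    assert classify_relationship(res) == expected


class TestBuildPairs:
    @staticmethod
    def _ped(rows):
        return pd.DataFrame(rows, columns=["family_id", "individual_id",
                                           "role", "sex", "birth_year"])

    def _po(self, a, b):
        return KinshipResult(a, b, 0.25, 0.0005, 10_000,
                             degree="parent_offspring")

    def test_birth_year_gap_rule(self):
        ped = self._ped([
            ("f1", "p15", "mother", "F", 1960),
            ("f1", "c15", "offspring", "F", 1975),   # gap 15: removed
            ("f2", "p16", "mother", "F", 1960),
            ("f2", "c16", "offspring", "M", 1976),   # gap 16: retained
            ("f3", "pt", "mother", "F", 1960),
            ("f3", "ct", "offspring", "M", 1960),    # tie: removed
        ])
        rel = [self._po("p15", "c15"), self._po("c16", "p16"),
               self._po("pt", "ct")]
        pairs = build_pairs(rel, ped)
        assert len(pairs.table) == 1
        row = pairs.table.iloc[0]
        assert (row.parent_id, row.offspring_id) == ("p16", "c16")
        assert row.parent_role == "mother"

    def test_parent_with_multiple_offspring(self):
        ped = self._ped(
            [("f", "mum", "mother", "F", 1950)]
            + [("f", f"kid{i}", "offspring", "M", 1975 + i)
               for i in range(3)])
        rel = [self._po("mum", f"kid{i}") for i in range(3)]
        pairs = build_pairs(rel, ped)
        assert pairs.n_mother_offspring == 3
        assert set(pairs.table.parent_id) == {"mum"}

    def test_father_role_from_sex(self):
        ped = self._ped([("f", "dad", "father", "M", 1950),
                         ("f", "kid", "offspring", "F", 1980)])
        pairs = build_pairs([self._po("kid", "dad")], ped)
        assert pairs.n_father_offspring == 1

    def test_missing_birth_year_warns_and_skips(self):
        ped = self._ped([("f", "p", "mother", "F", np.nan),
                         ("f", "c", "offspring", "F", 1980)])
        with pytest.warns(UserWarning, match="birth year"):
            pairs = build_pairs([self._po("p", "c")], ped)
        assert pairs.table.empty
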