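import numpy as np
import pandas as pd
import pytest

from triomr import SimConfig, simulate_cohort


@pytest.fixture(scope="session")
def base_cohort():
    """Mid-sized cohort with sibships, phenotypes and missing dosages."""
    cfg = SimConfig(n_families=300, n_background_snps=60,
                    genotype_missing_rate=0.01, seed=11)
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def kinship_cohort():
    """Cohort sized for genotype-based relationship inference: many SNPs,
    guaranteed sibships, no missingness."""
    cfg = SimConfig(n_families=120, offspring_dist={1: 0.3, 2: 0.5, 3: 0.2},
                    n_maternal_only=0, n_maternal_fetal=0, n_fetal_only=0,
                    n_background_snps=10_000, polygenic_h2=0.0,
                    fetal_bw_h2=0.0, fetal_pleiotropy_h2=0.0, gamma=0.0,
                    lambda2=0.0, seed=7)
    # score SNPs are not needed; keep one so the config validates
    cfg.n_maternal_only = 1
    from triomr import simulate_genotypes
    return simulate_genotypes(cfg)


def pedigree_pairs(cohort, parent_role="mother"):
    """True-pedigree parent-offspring pairs for a simulated cohort."""
    ped = cohort.pedigree
    off = ped[ped.role == "offspring"]
    parents = ped[ped.role == parent_role].set_index("family_id")[
        "individual_id"]
    return pd.DataFrame({
        "parent_id": parents.loc[off["family_id"]].to_numpy(),
        "offspring_id": off["individual_id"].to_numpy(),
        "parent_role": parent_role,
    })


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
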