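import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from famprs import (
    FamilyCohort,
    Pedigree,
    SimulationConfig,
    kinship_from_pedigree,
    simulate_cohort,
    single_snp_scan,
)
from famprs.mixedmodels import RandomEffectStructure


@pytest.fixture(scope="session")
def demo_cohort() -> FamilyCohort:
    """Small ascertained family cohort shared by read-only tests."""
    cfg = SimulationConfig(n_families=40, n_snps=20, seed=11)
    return simulate_cohort(cfg)


def make_unrelated_cohort(bmi: np.ndarray, seed: int = 0) -> FamilyCohort:
    """Cohort of singleton 'families' with given BMI values and one dummy SNP."""
    n = len(bmi)
    rng = np.random.default_rng(seed)
    ped = Pedigree(
        pd.DataFrame(
            {
                "fid": [f"F{i}" for i in range(n)],
                "iid": [f"I{i}" for i in range(n)],
                "father": [""] * n,
                "mother": [""] * n,
                "sex": rng.integers(1, 3, size=n),
            }
        )
    )
    phen = pd.DataFrame(
        {
            "iid": ped.ids,
            "bmi": bmi,
            "sex": ped.table["sex"].to_numpy(),
            "age": rng.uniform(20, 60, size=n),
        }
    )
    meta = pd.DataFrame(
        {"snp_id": ["snp0001"], "counted_allele": ["A"], "other_allele": ["G"],
         "maf": [0.3], "imputation_r2": [np.nan]}
    )
    geno = rng.binomial(2, 0.3, size=(n, 1)).astype(float)
    return FamilyCohort(pedigree=ped, genotypes=geno, snp_meta=meta, phenotypes=phen)


def simulate_family_outcome(
    structure: RandomEffectStructure,
    a: np.ndarray,
    rng: np.random.Generator,
    intercept: float = -1.0,
    beta_g: float = 0.0,
    g: np.ndarray | None = None,
    sigma_g2: float = 0.5,
) -> np.ndarray:
    """Binary outcome from a logistic model with kinship-structured random
    intercepts, drawn blockwise."""
    n = a.shape[0]
    u = np.zeros(n)
    for idx in structure.blocks:
        block = sigma_g2 * a[np.ix_(idx, idx)] + 1e-10 * np.eye(len(idx))
        u[idx] = np.linalg.cholesky(block) @ rng.standard_normal(len(idx))
    eta = intercept + u + (beta_g * g if g is not None else 0.0)
    return (rng.random(n) < expit(eta)).astype(float)


@pytest.fixture(scope="session")
def null_scan_pvalues() -> np.ndarray:
    """2000 single-SNP scan p-values under the null of no SNP effect.

    Ten base family cohorts provide genotypes and pedigrees; for each, 200
    binary outcomes are redrawn from a logistic model with a family random
    effect (sigma_g^2 = 0.5) and no genotype effect, and the scan's Wald
    p-value for the candidate SNP is recorded.
    """
    pvals = []
    for base in range(10):
        cfg = SimulationConfig(
            n_families=40, n_snps=1, h2_score=0.0, maf_range=(0.25, 0.25),
            missing_rate=0.0, seed=5_000 + base,
        )
        cohort = simulate_cohort(cfg, ascertain=False)
        kin = kinship_from_pedigree(cohort.pedigree)
        a = 2.0 * kin.matrix
        structure = RandomEffectStructure(a, family_ids=cohort.pedigree.family_ids)
        rng = np.random.default_rng(60_000 + base)
        for _ in range(200):
            y = simulate_family_outcome(structure, a, rng)
            if y.min() == y.max():
                continue
            cohort.phenotypes["obesity"] = y.astype(int)
            res = single_snp_scan(cohort, kin)
            pvals.append(res[0].p)
    return np.asarray(pvals)
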