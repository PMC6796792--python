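"""Single-SNP logistic mixed-model association scan for obesity.

Each SNP is tested under an additive model of inheritance: genotype coded as
the count (0/1/2) of the counted allele, entered as a fixed effect next to
sex and age, with the pedigree relationship matrix as random-effect
covariance. Odds ratios are per counted allele; p-values are two-sided Wald.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import FamilyCohort
from .kinship import KinshipMatrix
from .mixedmodels import RandomEffectStructure, fit_logistic_mixed

__all__ = ["AssocResult", "single_snp_scan", "assoc_frame", "mean_impute"]


@dataclass
class AssocResult:
    snp_id: str
    counted_allele: str
    beta: float  # log-odds per counted allele
    se: float
    odds_ratio: float
    p: float
    freq_case: float
    freq_control: float
    converged: bool
    separation: bool = False
    skipped: bool = False
    skip_reason: str = ""


def mean_impute(g: np.ndarray) -> tuple[np.ndarray, float]:
    """Replace missing genotype calls with 2 * counted-allele frequency.

    Returns the imputed column and the counted-allele frequency among
    observed calls.
    """
    g = np.asarray(g, dtype=float)
    obs = ~np.isnan(g)
    freq = float(g[obs].sum() / (2.0 * obs.sum())) if obs.any() else float("nan")
    out = g.copy()
    out[~obs] = 2.0 * freq
    return out, freq


def single_snp_scan(
    cohort: FamilyCohort,
    kin: KinshipMatrix,
    alpha: float = 0.05,
) -> list[AssocResult]:
    """Fit one logistic mixed model per SNP; results in SNP input order.

    Monomorphic SNPs are skipped with a reason instead of fitted. The
    significant set at level ``alpha`` is ``[r for r in results if not
    r.skipped and r.p < alpha]``.
    """
    structure = RandomEffectStructure(2.0 * kin.matrix, family_ids=cohort.pedigree.family_ids)
    y = cohort.obesity.astype(float)
    base = cohort.covariate_matrix()
    cases = y == 1
    results: list[AssocResult] = []
    for j in range(cohort.n_snps):
        snp_id = str(cohort.snp_meta["snp_id"].iloc[j])
        allele = str(cohort.snp_meta["counted_allele"].iloc[j])
        g_raw = cohort.genotypes[:, j]
        obs = ~np.isnan(g_raw)
        fc = float(np.nanmean(g_raw[cases]) / 2.0) if (cases & obs).any() else float("nan")
        f0 = float(np.nanmean(g_raw[~cases]) / 2.0) if (~cases & obs).any() else float("nan")
        g, _ = mean_impute(g_raw)
        if np.nanstd(g) == 0 or not obs.any():
            results.append(
                AssocResult(snp_id, allele, np.nan, np.nan, np.nan, np.nan, fc, f0,
                            converged=False, skipped=True, skip_reason="monomorphic")
            )
            continue
        fit = fit_logistic_mixed(y, np.column_stack([base, g]), structure)
        beta = float(fit.beta[-1])
        results.append(
            AssocResult(
                snp_id=snp_id,
                counted_allele=allele,
                beta=beta,
                se=float(fit.se[-1]),
                odds_ratio=float(np.exp(beta)),
                p=fit.wald_p(-1),
                freq_case=fc,
                freq_control=f0,
                converged=fit.converged,
                separation=fit.separation,
            )
        )
    return results


def assoc_frame(results: list[AssocResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "snp_id": [r.snp_id for r in results],
            "allele": [r.counted_allele for r in results],
            "beta": [r.beta for r in results],
            "se": [r.se for r in results],
            "OR": [r.odds_ratio for r in results],
            "p": [r.p for r in results],
            "freq_case": [r.freq_case for r in results],
            "freq_control": [r.freq_control for r in results],
            "converged": [r.converged for r in results],
            "skipped": [r.skipped for r in results],
        }
    )
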