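"""Per-SNP quality control: MAF, call rate, Hardy-Weinberg, imputation quality.

Filters reproduce the usual candidate-SNP inclusion rules with strict
inequalities: a SNP passes only if MAF > 1%, call rate > 95%,
HWE exact P > 2.6e-4, and (when an imputation r2 is recorded) r2 > 0.3.
Boundary values fail.

The HWE test is the conditional exact test: with the total genotype count and
allele counts fixed, the probability of each possible heterozygote count is

    P(n_Aa | n, n_A) = 2^{n_Aa} n! n_A! n_a! / ( n_AA! n_Aa! n_aa! (2n)! )

and the two-sided p-value sums the probabilities of all heterozygote counts
whose probability does not exceed that of the observed table (standard
two-sided rule, not mid-p).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd

from .cohort import FamilyCohort, ParameterError

__all__ = [
    "QCThresholds",
    "SNPQCRecord",
    "compute_maf_callrate",
    "hwe_exact_test",
    "hwe_chisq_test",
    "genotype_counts",
    "apply_qc",
    "filter_cohort",
    "qc_report_frame",
]


@dataclass(frozen=True)
class QCThresholds:
    min_maf: float = 0.01
    min_call_rate: float = 0.95
    min_hwe_p: float = 2.6e-4
    min_imputation_r2: float = 0.3

    def __post_init__(self) -> None:
        for name in ("min_maf", "min_call_rate", "min_hwe_p", "min_imputation_r2"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ParameterError(f"{name} must be in [0, 1]")


@dataclass
class SNPQCRecord:
    snp_id: str
    maf: float  # NaN when undefined (all calls missing)
    call_rate: float
    hwe_p: float
    imputation_r2: float | None
    passed: bool = True
    fail_reasons: list[str] = field(default_factory=list)


def compute_maf_callrate(genotype_column: np.ndarray) -> tuple[float, float]:
    """Minor-allele frequency and call rate of one SNP column.

    The allele frequency is computed over non-missing alleles and folded to
    min(f, 1-f). An all-missing column yields call rate 0 and MAF NaN.
    """
    g = np.asarray(genotype_column, dtype=float)
    obs = g[~np.isnan(g)]
    if obs.size and not np.isin(obs, (0.0, 1.0, 2.0)).all():
        raise ParameterError("genotype values must be in {0, 1, 2, missing}")
    call_rate = obs.size / g.size if g.size else 0.0
    if obs.size == 0:
        return float("nan"), float(call_rate)
    f = obs.sum() / (2.0 * obs.size)
    return float(min(f, 1.0 - f)), float(call_rate)


def genotype_counts(genotype_column: np.ndarray) -> tuple[int, int, int]:
    """(n_hom_counted, n_het, n_hom_other) among non-missing calls."""
    g = np.asarray(genotype_column, dtype=float)
    obs = g[~np.isnan(g)]
    return int((obs == 2).sum()), int((obs == 1).sum()), int((obs == 0).sum())


@lru_cache(maxsize=100_000)
def _het_distribution(n: int, n_rare: int) -> np.ndarray:
    """Probabilities of each feasible heterozygote count given n genotypes and
    n_rare copies of the rarer allele. Index k corresponds to n_het = lo + 2k,
    with lo = n_rare % 2. Computed by the stable two-term recurrence in the
    heterozygote count, then normalised."""
    lo = n_rare % 2
    hets = np.arange(lo, n_rare + 1, 2)
    probs = np.empty(hets.size)
    probs[0] = 1.0
    for i in range(1, hets.size):
        h = hets[i]
        n_aa = (n_rare - h) // 2  # rare homozygotes at het count h
        n_bb = n - h - n_aa
        # P(h) / P(h-2) = 4 * n_aa_prev * n_bb_prev / (h * (h - 1))
        probs[i] = probs[i - 1] * 4.0 * (n_aa + 1) * (n_bb + 1) / (h * (h - 1.0))
        if probs[i] > 1e280:  # rescale to avoid overflow; normalised below
            probs[: i + 1] /= probs[i]
    probs /= probs.sum()
    return probs


def hwe_exact_test(n_hom1: int, n_het: int, n_hom2: int) -> float:
    """Exact two-sided Hardy-Weinberg p-value for one biallelic SNP.

    ``n_hom1``/``n_hom2`` are the two homozygote counts and ``n_het`` the
    heterozygote count. Returns p in (0, 1]; a monomorphic SNP (single
    possible table) gives p = 1.
    """
    for c in (n_hom1, n_het, n_hom2):
        if c < 0 or int(c) != c:
            raise ParameterError("genotype counts must be non-negative integers")
    n_hom1, n_het, n_hom2 = int(n_hom1), int(n_het), int(n_hom2)
    n = n_hom1 + n_het + n_hom2
    if n == 0:
        raise ParameterError("total genotype count must be > 0")
    n_rare = min(2 * n_hom1 + n_het, 2 * n_hom2 + n_het)
    probs = _het_distribution(n, n_rare)
    k = (n_het - n_rare % 2) // 2
    p_obs = probs[k]
    # relative tolerance so that exact ties survive floating-point rounding
    p = probs[probs <= p_obs * (1.0 + 1e-10)].sum()
    return float(min(p, 1.0))


def hwe_chisq_test(n_hom1: int, n_het: int, n_hom2: int) -> float:
    """One-df chi-square HWE test (no continuity correction); for parity with
    array-pipeline defaults, not used by the default filters."""
    from scipy.stats import chi2

    n = n_hom1 + n_het + n_hom2
    if n == 0:
        raise ParameterError("total genotype count must be > 0")
    p = (2 * n_hom1 + n_het) / (2.0 * n)
    exp = np.array([n * p**2, 2 * n * p * (1 - p), n * (1 - p) ** 2])
    obs = np.array([n_hom1, n_het, n_hom2], dtype=float)
    if (exp == 0).any():
        return 1.0
    stat = ((obs - exp) ** 2 / exp).sum()
    return float(chi2.sf(stat, 1))


def apply_qc(
    cohort: FamilyCohort,
    thresholds: QCThresholds = QCThresholds(),
    founders_only: bool = True,
    hwe_method: str = "exact",
) -> list[SNPQCRecord]:
    """Evaluate every SNP against the inclusion filters; report-only.

    MAF and HWE are computed on pedigree founders by default, since genotype
    copies transmitted within families inflate naive allele-frequency and HWE
    statistics; ``founders_only=False`` uses all individuals for parity with
    pipelines that ignore relatedness. Call rate always uses all individuals.
    ``fail_reasons`` lists every violated filter (subset of
    {"maf", "call_rate", "hwe", "imputation_r2"}).
    """
    if hwe_method not in ("exact", "chisq"):
        raise ParameterError("hwe_method must be 'exact' or 'chisq'")
    hwe = hwe_exact_test if hwe_method == "exact" else hwe_chisq_test
    rows = cohort.pedigree.is_founder if founders_only else np.ones(cohort.n_individuals, bool)
    sub = cohort.genotypes[rows]
    has_r2 = "imputation_r2" in cohort.snp_meta.columns
    records: list[SNPQCRecord] = []
    for j in range(cohort.n_snps):
        maf, _ = compute_maf_callrate(sub[:, j])
        _, call_rate = compute_maf_callrate(cohort.genotypes[:, j])
        counts = genotype_counts(sub[:, j])
        hwe_p = hwe(*counts) if sum(counts) > 0 else float("nan")
        r2 = cohort.snp_meta["imputation_r2"].iloc[j] if has_r2 else None
        if r2 is not None and np.isnan(r2):
            r2 = None
        reasons = []
        if not (maf > thresholds.min_maf):  # NaN MAF fails too
            reasons.append("maf")
        if not (call_rate > thresholds.min_call_rate):
            reasons.append("call_rate")
        if not (hwe_p > thresholds.min_hwe_p):
            reasons.append("hwe")
        if r2 is not None and not (r2 > thresholds.min_imputation_r2):
            reasons.append("imputation_r2")
        records.append(
            SNPQCRecord(
                snp_id=str(cohort.snp_meta["snp_id"].iloc[j]),
                maf=maf,
                call_rate=call_rate,
                hwe_p=hwe_p,
                imputation_r2=None if r2 is None else float(r2),
                passed=not reasons,
                fail_reasons=reasons,
            )
        )
    return records


def filter_cohort(cohort: FamilyCohort, records: list[SNPQCRecord]) -> FamilyCohort:
    """Drop SNPs whose QC record failed."""
    keep = np.flatnonzero([r.passed for r in records])
    return cohort.subset_snps(keep)


def qc_report_frame(records: list[SNPQCRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "snp_id": [r.snp_id for r in records],
            "maf": [r.maf for r in records],
            "call_rate": [r.call_rate for r in records],
            "hwe_p": [r.hwe_p for r in records],
            "imputation_r2": [np.nan if r.imputation_r2 is None else r.imputation_r2 for r in records],
            "pass": [r.passed for r in records],
            "fail_reasons": [",".join(r.fail_reasons) for r in records],
        }
    )
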