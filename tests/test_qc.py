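import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import gammaln

from famprs import (
    FamilyCohort,
    ParameterError,
    QCThresholds,
    apply_qc,
    compute_maf_callrate,
    hwe_exact_test,
)
from famprs.qc import filter_cohort, genotype_counts, hwe_chisq_test, qc_report_frame

from conftest import make_unrelated_cohort


def hwe_enumeration_oracle(n_hom1: int, n_het: int, n_hom2: int) -> float:
    """Independent brute force: log-gamma probability of every heterozygote
    count compatible with the fixed allele counts."""
    n = n_hom1 + n_het + n_hom2
    n_a = 2 * n_hom1 + n_het
    n_b = 2 * n_hom2 + n_het
    rare = min(n_a, n_b)
    lo = rare % 2
    hets = np.arange(lo, rare + 1, 2)
    aa = (rare - hets) // 2
    bb = n - hets - aa
    logp = (
        hets * np.log(2.0)
        + gammaln(n + 1) - gammaln(aa + 1) - gammaln(hets + 1) - gammaln(bb + 1)
        + gammaln(n_a + 1) + gammaln(n_b + 1) - gammaln(2 * n + 1)
    )
    probs = np.exp(logp - logp.max())
    probs /= probs.sum()
    p_obs = probs[(n_het - lo) // 2]
    return float(probs[probs <= p_obs * (1 + 1e-10)].sum())


class TestMafCallRate:
    def test_arithmetic_example(self):
        maf, cr = compute_maf_callrate(np.array([0, 1, 2, 2.0]))
        assert maf == pytest.approx(0.375)
        assert cr == 1.0

    def test_all_missing_flags_not_crashes(self):
        maf, cr = compute_maf_callrate(np.array([np.nan, np.nan]))
        assert cr == 0.0
        assert np.isnan(maf)

    def test_binomial_sampling(self):
        rng = np.random.default_rng(8)
        col = rng.binomial(2, 0.2, size=1000).astype(float)
        maf, cr = compute_maf_callrate(col)
        se = np.sqrt(0.2 * 0.8 / 2000)
        assert abs(maf - 0.2) < 3 * se
        assert cr == 1.0

    def test_invalid_values_rejected(self):
        with pytest.raises(ParameterError):
            compute_maf_callrate(np.array([0.0, 3.0]))


class TestHWEExact:
    def test_monomorphic_is_one(self):
        assert hwe_exact_test(0, 0, 50) == 1.0
        assert hwe_exact_test(50, 0, 0) == 1.0

    def test_modal_het_count_is_one(self):
        # find the modal heterozygote count for n=100, 60 rare alleles
        n, rare = 100, 60
        best = max(
            range(rare % 2, rare + 1, 2),
            key=lambda h: hwe_enumeration_probs(n, rare)[(h - rare % 2) // 2],
        )
        aa = (rare - best) // 2
        assert hwe_exact_test(aa, best, n - best - aa) == pytest.approx(1.0)

    def test_example_counts_match_enumeration(self):
        assert hwe_exact_test(57, 78, 13) == pytest.approx(
            hwe_enumeration_oracle(57, 78, 13), abs=1e-12
        )

    def test_negative_counts_rejected(self):
        with pytest.raises(ParameterError):
            hwe_exact_test(-1, 2, 3)
        with pytest.raises(ParameterError):
            hwe_exact_test(0, 0, 0)

    @given(
        n=st.integers(1, 120),
        f1=st.floats(0, 1),
        f2=st.floats(0, 1),
    )
    @settings(max_examples=150, deadline=None)
    def test_matches_oracle_and_in_unit_interval(self, n, f1, f2):
        n_hom1 = int(round(f1 * n))
        n_het = int(round(f2 * (n - n_hom1)))
        n_hom2 = n - n_hom1 - n_het
        p = hwe_exact_test(n_hom1, n_het, n_hom2)
        assert 0.0 < p <= 1.0
        assert p == pytest.approx(hwe_enumeration_oracle(n_hom1, n_het, n_hom2), abs=1e-12)

    def test_symmetry_in_allele_labels(self):
        assert hwe_exact_test(30, 40, 10) == hwe_exact_test(10, 40, 30)

    def test_chisq_variant_close_for_large_counts(self):
        p_exact = hwe_exact_test(500, 480, 120)
        p_chi = hwe_chisq_test(500, 480, 120)
        assert abs(p_exact - p_chi) < 0.05


def hwe_enumeration_probs(n: int, rare: int) -> np.ndarray:
    lo = rare % 2
    hets = np.arange(lo, rare + 1, 2)
    aa = (rare - hets) // 2
    bb = n - hets - aa
    logp = (
        hets * np.log(2.0)
        + gammaln(n + 1) - gammaln(aa + 1) - gammaln(hets + 1) - gammaln(bb + 1)
    )
    probs = np.exp(logp - logp.max())
    return probs / probs.sum()


def _qc_cohort():
    """Eight founders, five SNPs crafted to hit each filter."""
    rng = np.random.default_rng(3)
    co = make_unrelated_cohort(rng.normal(25, 4, size=400), seed=3)
    geno = np.column_stack(
        [
            rng.binomial(2, 0.3, 400).astype(float),  # clean
            np.zeros(400),  # maf 0 -> fails maf (and is monomorphic)
            rng.binomial(2, 0.3, 400).astype(float),  # call-rate failure below
            rng.binomial(2, 0.25, 400).astype(float),  # low imputation r2
            np.tile([0.0, 2.0], 200),  # no hets: extreme HWE failure
        ]
    )
    geno[: 40, 2] = np.nan  # call rate 0.9
    meta = pd.DataFrame(
        {
            "snp_id": [f"s{i}" for i in range(5)],
            "counted_allele": ["A"] * 5,
            "other_allele": ["G"] * 5,
            "maf": [0.3, 0.0, 0.3, 0.25, 0.5],
            "imputation_r2": [np.nan, np.nan, np.nan, 0.2, np.nan],
        }
    )
    return FamilyCohort(
        pedigree=co.pedigree,
        genotypes=geno,
        snp_meta=meta,
        phenotypes=co.phenotypes,
    )


class TestApplyQC:
    def test_fail_reasons_enumerate_filters(self):
        records = apply_qc(_qc_cohort())
        by_id = {r.snp_id: r for r in records}
        assert by_id["s0"].passed and by_id["s0"].fail_reasons == []
        assert by_id["s1"].fail_reasons == ["maf"]
        assert by_id["s2"].fail_reasons == ["call_rate"]
        assert by_id["s3"].fail_reasons == ["imputation_r2"]
        assert "hwe" in by_id["s4"].fail_reasons
        for r in records:
            assert r.passed == (len(r.fail_reasons) == 0)

    def test_strict_boundaries_fail(self):
        """A value exactly at the printed threshold does not pass."""
        n = 400
        rng = np.random.default_rng(5)
        co = make_unrelated_cohort(rng.normal(25, 4, n), seed=5)
        geno = np.column_stack([
            np.concatenate([np.ones(8), np.zeros(n - 8)]),  # maf exactly 0.01
            rng.binomial(2, 0.3, n).astype(float),
        ])
        geno[: n // 20, 1] = np.nan  # call rate exactly 0.95
        meta = pd.DataFrame({
            "snp_id": ["m", "c"], "counted_allele": ["A"] * 2,
            "other_allele": ["G"] * 2, "maf": [0.01, 0.3],
            "imputation_r2": [np.nan, 0.3],  # r2 exactly at threshold
        })
        cohort = FamilyCohort(co.pedigree, geno, meta, co.phenotypes)
        by_id = {r.snp_id: r for r in apply_qc(cohort)}
        assert "maf" in by_id["m"].fail_reasons
        assert "call_rate" in by_id["c"].fail_reasons
        assert "imputation_r2" in by_id["c"].fail_reasons

    def test_idempotent(self):
        cohort = _qc_cohort()
        records = apply_qc(cohort)
        surviving = filter_cohort(cohort, records)
        again = apply_qc(surviving)
        assert all(r.passed for r in again)
        assert filter_cohort(surviving, again).n_snps == surviving.n_snps

    def test_founders_only_vs_all(self, demo_cohort):
        rec_f = apply_qc(demo_cohort, founders_only=True)
        rec_a = apply_qc(demo_cohort, founders_only=False)
        assert len(rec_f) == len(rec_a) == demo_cohort.n_snps
        frame = qc_report_frame(rec_f)
        assert list(frame.columns) == [
            "snp_id", "maf", "call_rate", "hwe_p", "imputation_r2", "pass", "fail_reasons",
        ]

    def test_genotype_counts(self):
        assert genotype_counts(np.array([0, 1, 1, 2, np.nan])) == (1, 2, 1)

    def test_threshold_validation(self):
        with pytest.raises(ParameterError):
            QCThresholds(min_maf=-0.1)
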