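"""Per-SNP quality control: MAF, call rate, Hardy-Weinberg, imputation r2.

Filters follow the usual candidate-SNP inclusion rules with strict
inequalities (MAF > 1%, call rate > 95%, HWE exact P > 2.6e-4, imputation
r2 > 0.3 where recorded). MAF and HWE are computed on founders so that
within-family allele copies do not distort them.
"""

from famprs import SimulationConfig, apply_qc, hwe_exact_test, simulate_cohort
from famprs.qc import filter_cohort, qc_report_frame

cohort = simulate_cohort(SimulationConfig(n_families=120, seed=3, missing_rate=0.02))
records = apply_qc(cohort)

report = qc_report_frame(records)
print(report.head(8).to_string(index=False))
n_pass = int(report["pass"].sum())
print(f"\n{n_pass}/{len(report)} SNPs pass all filters")
print("fail reasons seen:", sorted(set(",".join(report["fail_reasons"]).split(",")) - {""}))

filtered = filter_cohort(cohort, records)
print(f"filtered cohort keeps {filtered.n_snps} SNP columns")

p = hwe_exact_test(57, 78, 13)
print(f"\nHWE exact test for genotype counts (57, 78, 13): P = {p:.4f}")
print("large P means the genotype proportions are compatible with random mating")
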