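"""Weighted polygenic risk score construction and quintile assignment.

The score of individual i is sum_j w_j * g_ij over the scored SNPs, with
g_ij the counted-allele count and missing calls replaced by twice the
counted-allele frequency. The default weighting multiplies allele counts by
the per-SNP odds ratio itself (the construction this pipeline reproduces);
the field-standard log-odds weighting is available as ``mode="logOR"``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .association import AssocResult, mean_impute
from .cohort import FamilyCohort, ParameterError

__all__ = ["ScoreWeights", "PRSVector", "build_weights", "compute_prs", "assign_quintiles"]

QUINTILE_LABELS = ["Q1", "Q2", "Q3", "Q4", "Q5"]


@dataclass
class ScoreWeights:
    table: pd.DataFrame  # columns: snp_id, allele, weight
    mode: str = "OR"

    def __post_init__(self) -> None:
        if self.mode not in ("OR", "logOR"):
            raise ParameterError("weighting mode must be 'OR' or 'logOR'")
        need = {"snp_id", "allele", "weight"}
        if not need.issubset(self.table.columns):
            raise ParameterError(f"weight table must have columns {sorted(need)}")
        w = self.table["weight"].to_numpy(dtype=float)
        if not np.isfinite(w).all():
            raise ParameterError("weights must be finite")
        if self.mode == "OR" and (w <= 0).any():
            raise ParameterError("OR-mode weights must be positive")


@dataclass
class PRSVector:
    values: np.ndarray
    iids: np.ndarray | None = None
    quintile: np.ndarray | None = None  # labels Q1..Q5 once assigned

    def to_frame(self) -> pd.DataFrame:
        out = pd.DataFrame({"prs": self.values})
        if self.iids is not None:
            out.insert(0, "iid", self.iids)
        if self.quintile is not None:
            out["quintile"] = self.quintile
        return out


def build_weights(assoc: list[AssocResult], mode: str = "OR") -> ScoreWeights:
    """Turn per-SNP association results into score weights.

    ``mode="OR"`` uses the odds ratio as weight; ``mode="logOR"`` its log.
    Skipped SNPs (e.g. monomorphic) are excluded; a non-skipped SNP without
    an odds ratio raises an error naming it.
    """
    rows = []
    for r in assoc:
        if r.skipped:
            continue
        if not np.isfinite(r.odds_ratio):
            raise ParameterError(f"SNP {r.snp_id} has no odds ratio")
        w = r.odds_ratio if mode == "OR" else float(np.log(r.odds_ratio))
        rows.append((r.snp_id, r.counted_allele, w))
    return ScoreWeights(pd.DataFrame(rows, columns=["snp_id", "allele", "weight"]), mode=mode)


def compute_prs(cohort: FamilyCohort, weights: ScoreWeights) -> PRSVector:
    """Deterministic weighted allele sum across the weight SNPs.

    Genotype columns are matched by snp_id; if the weight's counted allele is
    the cohort's *other* allele, the genotype is flipped (g -> 2 - g) before
    weighting. Missing genotypes contribute ``w * 2 * frequency``.
    """
    meta = cohort.snp_meta
    col_of = {str(s): j for j, s in enumerate(meta["snp_id"])}
    missing = [s for s in weights.table["snp_id"] if s not in col_of]
    if missing:
        raise ParameterError(f"weight SNPs absent from genotypes: {missing}")
    score = np.zeros(cohort.n_individuals)
    for snp_id, allele, w in weights.table.itertuples(index=False):
        j = col_of[str(snp_id)]
        g, _ = mean_impute(cohort.genotypes[:, j])
        counted = str(meta["counted_allele"].iloc[j])
        other = str(meta["other_allele"].iloc[j]) if "other_allele" in meta.columns else None
        if allele != counted:
            if other is not None and allele != other:
                raise ParameterError(
                    f"weight allele {allele!r} matches neither allele of {snp_id}"
                )
            g = 2.0 - g
        score += w * g
    return PRSVector(values=score, iids=cohort.pedigree.ids.copy())


def assign_quintiles(prs: PRSVector) -> PRSVector:
    """Rank-based split into five groups; Q1 holds the lowest scores.

    Group sizes are ceil(n/5) or floor(n/5) (the larger groups come first);
    ties are broken by stable input order, so identical values still yield
    balanced groups.
    """
    n = len(prs.values)
    if n < 5:
        raise ParameterError("need at least 5 individuals for quintiles")
    order = np.argsort(prs.values, kind="stable")
    labels = np.empty(n, dtype=object)
    for q, chunk in enumerate(np.array_split(order, 5)):
        labels[chunk] = QUINTILE_LABELS[q]
    return PRSVector(values=prs.values, iids=prs.iids, quintile=labels)
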