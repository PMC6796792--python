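"""Core containers: pedigrees, simulated/loaded family cohorts, simulation config.

A :class:`FamilyCohort` keeps pedigree rows, the genotype matrix, per-SNP
metadata and per-individual phenotypes aligned on a single individual order;
every downstream stage (QC, kinship, association, scoring, evaluation)
consumes this object or slices of it.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

MISSING = np.nan

#: sex coding follows PED convention: 1 = male, 2 = female
MALE, FEMALE = 1, 2


class ParameterError(ValueError):
    """Invalid user-supplied parameter."""


class PedigreeError(ValueError):
    """Structurally invalid pedigree (cycles, dangling parent ids...)."""


@dataclass(frozen=True)
class Pedigree:
    """Nuclear/extended pedigree as a table of individuals.

    Columns of ``table``: ``fid`` (family), ``iid`` (individual), ``father``,
    ``mother`` (empty string for founders), ``sex`` (1 male / 2 female).
    Row order defines the individual order used by every aligned matrix.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = ["fid", "iid", "father", "mother", "sex"]
        missing = [c for c in required if c not in self.table.columns]
        if missing:
            raise PedigreeError(f"pedigree table missing columns: {missing}")
        tab = self.table.reset_index(drop=True)
        for col in ("fid", "iid", "father", "mother"):
            tab[col] = tab[col].astype(str)
        tab.loc[tab["father"].isin(("0", "nan", "None", "")), "father"] = ""
        tab.loc[tab["mother"].isin(("0", "nan", "None", "")), "mother"] = ""
        object.__setattr__(self, "table", tab)
        if tab["iid"].duplicated().any():
            dup = tab.loc[tab["iid"].duplicated(), "iid"].iloc[0]
            raise PedigreeError(f"duplicate individual id {dup!r}")
        ids = set(tab["iid"])
        for col in ("father", "mother"):
            bad = tab.loc[(tab[col] != "") & ~tab[col].isin(ids), col]
            if len(bad):
                raise PedigreeError(f"referenced {col} {bad.iloc[0]!r} not in pedigree")
        # a single known parent is allowed (the other is treated as an
        # unrelated founder), as in PED files after subsetting
        self.topological_order()  # raises on cycles

    # -- basic accessors -------------------------------------------------
    @property
    def ids(self) -> np.ndarray:
        return self.table["iid"].to_numpy()

    @property
    def family_ids(self) -> np.ndarray:
        return self.table["fid"].to_numpy()

    @property
    def n(self) -> int:
        return len(self.table)

    @property
    def is_founder(self) -> np.ndarray:
        return ((self.table["father"] == "") & (self.table["mother"] == "")).to_numpy()

    def index_of(self, iids: Sequence[str]) -> np.ndarray:
        pos = pd.Index(self.table["iid"])
        return pos.get_indexer(list(iids))

    def topological_order(self) -> np.ndarray:
        """Indices ordered so that parents precede offspring; cycle -> error."""
        tab = self.table
        idx = pd.Index(tab["iid"])
        parents = [
            [idx.get_loc(p) for p in (f, m) if p != ""]
            for f, m in zip(tab["father"], tab["mother"])
        ]
        order: list[int] = []
        state = np.zeros(len(tab), dtype=np.int8)  # 0 unseen, 1 in-stack, 2 done

        for start in range(len(tab)):
            if state[start]:
                continue
            stack = [(start, 0)]
            state[start] = 1
            while stack:
                node, k = stack.pop()
                ps = parents[node]
                if k < len(ps):
                    stack.append((node, k + 1))
                    p = ps[k]
                    if state[p] == 1:
                        raise PedigreeError("pedigree contains a cycle")
                    if state[p] == 0:
                        state[p] = 1
                        stack.append((p, 0))
                else:
                    state[node] = 2
                    order.append(node)
        return np.asarray(order)

    def subset(self, indices: np.ndarray) -> "Pedigree":
        """Keep the given rows; parent links to dropped individuals are cut."""
        tab = self.table.iloc[indices].reset_index(drop=True).copy()
        kept = set(tab["iid"])
        for col in ("father", "mother"):
            tab.loc[~tab[col].isin(kept), col] = ""
        return Pedigree(tab)


def _offspring_spec(value) -> tuple[int, int, float]:
    try:
        lo, hi, mean = value
    except Exception as exc:  # noqa: BLE001
        raise ParameterError("offspring_per_family must be (min, max, mean)") from exc
    lo, hi = int(lo), int(hi)
    mean = float(mean)
    if not (1 <= lo <= hi) or not (lo <= mean <= hi):
        raise ParameterError("offspring_per_family requires 1 <= min <= mean <= max")
    return lo, hi, mean


@dataclass
class SimulationConfig:
    """Parameters of the ascertained nuclear-family cohort generator.

    Defaults emulate the study conditions the generator stands in for:
    222 nuclear families (~881 individuals), 231 candidate SNPs with a
    common-variant MAF spectrum, families ascertained on at least one
    parent and one offspring with BMI >= 32 kg/m2, obesity defined as
    BMI >= 30 kg/m2, and a true polygenic score carrying 7.5% of BMI
    variance in the unascertained population.
    """

    n_families: int = 222
    offspring_per_family: tuple[int, int, float] = (1, 6, 1.97)
    n_snps: int = 231
    maf_range: tuple[float, float] = (0.05, 0.5)
    h2_score: float = 0.075
    effect_sizes: np.ndarray | None = None  # kg/m2 per counted allele; overrides h2_score scaling
    bmi_base_mean: float = 22.0  # population mean BMI, kg/m2 (calibrated for ~28% post-ascertainment obesity)
    bmi_base_sd: float = 6.5  # population BMI standard deviation, kg/m2
    sex_effect: float = 0.5  # kg/m2 added for males
    age_effect: float = 0.05  # kg/m2 per year (centred age)
    parent_age_range: tuple[float, float] = (35.0, 60.0)
    offspring_age_range: tuple[float, float] = (15.0, 35.0)
    ascertainment_bmi: float = 32.0
    recruitment_bmi_noise_sd: float = 6.0  # kg/m2 drift between recruitment-time and measured BMI
    obesity_threshold: float = 30.0
    missing_rate: float = 0.01
    fraction_imputed: float = 135.0 / 231.0
    imputation_r2_range: tuple[float, float] = (0.55, 1.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_families < 1:
            raise ParameterError("n_families must be >= 1")
        if self.n_snps < 1:
            raise ParameterError("n_snps must be >= 1")
        lo, hi = map(float, self.maf_range)
        if not (0.0 < lo <= hi <= 0.5):
            raise ParameterError("maf_range must lie in (0, 0.5]")
        if not (0.0 <= self.h2_score < 1.0):
            raise ParameterError("h2_score must be in [0, 1)")
        if self.bmi_base_sd <= 0:
            raise ParameterError("bmi_base_sd must be > 0")
        if self.ascertainment_bmi is not None and self.ascertainment_bmi < 0:
            raise ParameterError("ascertainment_bmi must be >= 0")
        if self.obesity_threshold <= 0:
            raise ParameterError("obesity_threshold must be > 0")
        if self.recruitment_bmi_noise_sd < 0:
            raise ParameterError("recruitment_bmi_noise_sd must be >= 0")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ParameterError("missing_rate must be in [0, 1)")
        if not (0.0 <= self.fraction_imputed <= 1.0):
            raise ParameterError("fraction_imputed must be in [0, 1]")
        _offspring_spec(self.offspring_per_family)
        if self.effect_sizes is not None:
            eff = np.asarray(self.effect_sizes, dtype=float)
            if eff.shape != (self.n_snps,):
                raise ParameterError("effect_sizes must have length n_snps")
            self.effect_sizes = eff

    def replace(self, **kwargs) -> "SimulationConfig":
        return dataclasses.replace(self, **kwargs)


@dataclass
class FamilyCohort:
    """Aligned pedigree + genotypes + phenotypes for a set of families.

    ``genotypes`` is an (n individuals x m SNPs) float matrix of counted-allele
    counts in {0, 1, 2} with NaN for missing calls. ``snp_meta`` has one row
    per SNP (snp_id, counted_allele, other_allele, maf, imputation_r2).
    ``phenotypes`` has one row per individual (iid, bmi, obesity, sex, age).
    ``true_score`` is the latent per-individual genetic value, present only
    for simulated cohorts.
    """

    pedigree: Pedigree
    genotypes: np.ndarray
    snp_meta: pd.DataFrame
    phenotypes: pd.DataFrame
    true_score: np.ndarray | None = None
    obesity_threshold: float = 30.0

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=float)
        n = self.pedigree.n
        if self.genotypes.shape[0] != n:
            raise ParameterError("genotype rows must match pedigree individuals")
        if self.genotypes.shape[1] != len(self.snp_meta):
            raise ParameterError("genotype columns must match snp_meta rows")
        if len(self.phenotypes) != n:
            raise ParameterError("phenotype rows must match pedigree individuals")
        vals = self.genotypes[~np.isnan(self.genotypes)]
        if vals.size and not np.isin(vals, (0.0, 1.0, 2.0)).all():
            raise ParameterError("genotype values must be in {0, 1, 2, missing}")
        self.phenotypes = self.phenotypes.reset_index(drop=True)
        self.snp_meta = self.snp_meta.reset_index(drop=True)
        if "obesity" not in self.phenotypes.columns and "bmi" in self.phenotypes.columns:
            self.phenotypes["obesity"] = (
                self.phenotypes["bmi"] >= self.obesity_threshold
            ).astype(int)

    @property
    def n_individuals(self) -> int:
        return self.pedigree.n

    @property
    def n_snps(self) -> int:
        return self.genotypes.shape[1]

    @property
    def obesity(self) -> np.ndarray:
        return self.phenotypes["obesity"].to_numpy(dtype=int)

    @property
    def bmi(self) -> np.ndarray:
        return self.phenotypes["bmi"].to_numpy(dtype=float)

    def covariate_matrix(self) -> np.ndarray:
        """Design columns [intercept, male indicator, age in years]."""
        sex = (self.phenotypes["sex"].to_numpy(dtype=int) == MALE).astype(float)
        age = self.phenotypes["age"].to_numpy(dtype=float)
        return np.column_stack([np.ones(self.n_individuals), sex, age])

    def subset_individuals(self, indices: np.ndarray) -> "FamilyCohort":
        indices = np.asarray(indices)
        return FamilyCohort(
            pedigree=self.pedigree.subset(indices),
            genotypes=self.genotypes[indices],
            snp_meta=self.snp_meta.copy(),
            phenotypes=self.phenotypes.iloc[indices].reset_index(drop=True),
            true_score=None if self.true_score is None else self.true_score[indices],
            obesity_threshold=self.obesity_threshold,
        )

    def subset_snps(self, snp_indices: np.ndarray) -> "FamilyCohort":
        snp_indices = np.asarray(snp_indices)
        return FamilyCohort(
            pedigree=self.pedigree,
            genotypes=self.genotypes[:, snp_indices],
            snp_meta=self.snp_meta.iloc[snp_indices].reset_index(drop=True),
            phenotypes=self.phenotypes.copy(),
            true_score=self.true_score,
            obesity_threshold=self.obesity_threshold,
        )

    def families(self) -> dict[str, np.ndarray]:
        """Mapping family id -> row indices, in first-appearance order."""
        fids = self.pedigree.family_ids
        out: dict[str, list[int]] = {}
        for i, f in enumerate(fids):
            out.setdefault(f, []).append(i)
        return {f: np.asarray(ix) for f, ix in out.items()}
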