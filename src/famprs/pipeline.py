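"""End-to-end orchestration: simulate/load -> QC -> kinship -> association ->
score -> stratification evaluation -> power, from one config object.

Every stochastic stage takes an explicit seed recorded in the report, so an
identical config yields a byte-identical JSON report.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from dataclasses import asdict, dataclass, field
from typing import Any

import numpy as np

from . import __version__
from .association import assoc_frame, single_snp_scan
from .cohort import FamilyCohort, ParameterError, SimulationConfig
from .evaluate import (
    AUCReport,
    NRIIDIReport,
    QuintileOR,
    TrendResult,
    VarianceExplained,
    nri_idi,
    optimism_bootstrap,
    quintile_or_test,
    trend_test,
    variance_explained,
)
from .kinship import kinship_from_pedigree
from .mixedmodels import RandomEffectStructure, fit_logistic_mixed
from .power import PowerInputs, analytic_power
from .prs import assign_quintiles, build_weights, compute_prs
from .qc import QCThresholds, apply_qc, filter_cohort, qc_report_frame
from .simulate import simulate_cohort, split_cohort

logger = logging.getLogger("famprs.pipeline")

__all__ = ["PipelineConfig", "PipelineReport", "run_all", "compute_prevalence"]


def compute_prevalence(case_count: int, n: int) -> float:
    """Prevalence as a percentage (unrounded); display rounds to one decimal."""
    if n <= 0:
        raise ParameterError("n must be > 0")
    if not (0 <= case_count <= n):
        raise ParameterError("case_count must be in [0, n]")
    return 100.0 * case_count / n


@dataclass
class PipelineConfig:
    simulation: SimulationConfig | None = None
    input_prefix: str | None = None  # artefacts of io.write_cohort
    thresholds: QCThresholds = field(default_factory=QCThresholds)
    founders_only_qc: bool = True
    split_fraction: float = 0.8
    split_seed: int = 1
    split_stratified: bool = True
    split_by_family: bool = False
    weight_mode: str = "OR"
    alpha: float = 0.05
    bootstrap_B: int = 1000
    bootstrap_seed: int = 1
    nri_B: int = 1000
    out_dir: str | None = None

    def __post_init__(self) -> None:
        if (self.simulation is None) == (self.input_prefix is None):
            raise ParameterError("exactly one genotype source: simulation or input_prefix")

    @classmethod
    def from_dict(cls, raw: dict[str, Any]) -> "PipelineConfig":
        raw = dict(raw)
        sim = raw.pop("simulation", None)
        if sim is not None:
            sim = SimulationConfig(**sim)
        thr = raw.pop("thresholds", None)
        thr = QCThresholds(**thr) if thr is not None else QCThresholds()
        return cls(simulation=sim, thresholds=thr, **raw)

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass
class PartitionReport:
    n: int
    n_cases: int
    prevalence_percent: float
    trend: TrendResult
    trend_per_sd: TrendResult
    quintile_ors: list[QuintileOR]
    auc: AUCReport
    nri_idi: NRIIDIReport
    variance_explained: VarianceExplained


@dataclass
class PipelineReport:
    version: str
    seeds: dict[str, int]
    n_snps_input: int
    n_snps_pass_qc: int
    n_significant_snps: int
    discovery: PartitionReport
    validation: PartitionReport
    power: dict[str, float]
    checksums: dict[str, str]

    def to_json(self) -> str:
        def default(o):
            if dataclasses.is_dataclass(o) and not isinstance(o, type):
                return asdict(o)
            if isinstance(o, (np.floating, np.integer)):
                return o.item()
            if isinstance(o, np.ndarray):
                return o.tolist()
            raise TypeError(type(o))

        return json.dumps(asdict(self), sort_keys=True, indent=1, default=default,
                          allow_nan=True)


def _md5(arr: np.ndarray) -> str:
    return hashlib.md5(np.ascontiguousarray(arr).tobytes()).hexdigest()


def _evaluate_partition(
    part: FamilyCohort, weights, cfg: PipelineConfig, seed_offset: int
) -> PartitionReport:
    kin = kinship_from_pedigree(part.pedigree)
    structure = RandomEffectStructure(2.0 * kin.matrix, family_ids=part.pedigree.family_ids)
    prs = compute_prs(part, weights)
    prs = assign_quintiles(prs)
    y = part.obesity
    sex = part.phenotypes["sex"].to_numpy()
    age = part.phenotypes["age"].to_numpy(dtype=float)

    trend = trend_test(prs.values, y, sex, age, structure)
    trend_sd = trend_test(prs.values, y, sex, age, structure, per_sd=True)
    quints = quintile_or_test(prs.quintile, y, sex, age, structure)

    base_x = part.covariate_matrix()
    full_x = np.column_stack([base_x, prs.values])
    auc_rep = optimism_bootstrap(
        y.astype(float), full_x, structure,
        B=cfg.bootstrap_B, seed=cfg.bootstrap_seed + seed_offset, x_base=base_x,
    )
    from scipy.special import expit

    fit_base = fit_logistic_mixed(y.astype(float), base_x, structure)
    fit_full = fit_logistic_mixed(y.astype(float), full_x, structure)
    p_old = expit(np.clip(base_x @ fit_base.beta, -30, 30))
    p_new = expit(np.clip(full_x @ fit_full.beta, -30, 30))
    nri = nri_idi(p_old, p_new, y, B=cfg.nri_B, seed=cfg.bootstrap_seed + seed_offset + 1)

    ve = variance_explained(part.bmi, prs.values, sex, age, structure)
    n_cases = int(y.sum())
    return PartitionReport(
        n=part.n_individuals,
        n_cases=n_cases,
        prevalence_percent=compute_prevalence(n_cases, part.n_individuals),
        trend=trend,
        trend_per_sd=trend_sd,
        quintile_ors=quints,
        auc=auc_rep,
        nri_idi=nri,
        variance_explained=ve,
    )


def run_all(config: PipelineConfig) -> PipelineReport:
    """Execute every stage in order; any stage error aborts with the stage name."""
    stage = "load"
    try:
        if config.simulation is not None:
            stage = "simulate"
            logger.info("stage=%s seed=%d", stage, config.simulation.seed)
            cohort = simulate_cohort(config.simulation)
        else:
            from .io import read_cohort

            logger.info("stage=%s prefix=%s", stage, config.input_prefix)
            cohort = read_cohort(config.input_prefix)

        checksums = {"genotypes": _md5(np.nan_to_num(cohort.genotypes, nan=-1.0)),
                     "bmi": _md5(cohort.bmi)}

        stage = "split"
        logger.info("stage=%s fraction=%.2f seed=%d", stage, config.split_fraction, config.split_seed)
        discovery, validation = split_cohort(
            cohort, config.split_fraction, config.split_seed,
            stratify_by_obesity=config.split_stratified,
            by_family=config.split_by_family,
        )

        stage = "qc"
        records = apply_qc(discovery, config.thresholds, founders_only=config.founders_only_qc)
        discovery_qc = filter_cohort(discovery, records)
        validation_qc = validation.subset_snps(
            np.flatnonzero([r.passed for r in records])
        )
        logger.info("stage=%s pass=%d/%d", stage, discovery_qc.n_snps, cohort.n_snps)

        stage = "association"
        kin_d = kinship_from_pedigree(discovery_qc.pedigree)
        assoc = single_snp_scan(discovery_qc, kin_d, alpha=config.alpha)
        n_sig = sum(1 for r in assoc if not r.skipped and r.p < config.alpha)
        logger.info("stage=%s significant=%d/%d", stage, n_sig, len(assoc))

        stage = "weights"
        weights = build_weights(assoc, mode=config.weight_mode)

        stage = "evaluate_discovery"
        rep_d = _evaluate_partition(discovery_qc, weights, config, seed_offset=0)
        stage = "evaluate_validation"
        rep_v = _evaluate_partition(validation_qc, weights, config, seed_offset=1000)

        stage = "power"
        pin = PowerInputs(
            n_train=rep_d.n,
            n_target=rep_v.n,
            prevalence_train=rep_d.n_cases / rep_d.n,
            prevalence_target=max(min(rep_v.n_cases / rep_v.n, 1 - 1e-9), 1e-9),
            n_snps=discovery_qc.n_snps,
            score_r2_train=min(rep_d.variance_explained.r2, 0.99),
            alpha=config.alpha,
        )
        pres = analytic_power(pin)
        power = {
            "n_train": float(pin.n_train),
            "n_target": float(pin.n_target),
            "score_r2_train": pin.score_r2_train,
            "rho2_target": pres.rho2_target,
            "ncp": pres.ncp,
            "power": pres.power,
        }

        report = PipelineReport(
            version=__version__,
            seeds={
                "simulation": config.simulation.seed if config.simulation else -1,
                "split": config.split_seed,
                "bootstrap": config.bootstrap_seed,
            },
            n_snps_input=cohort.n_snps,
            n_snps_pass_qc=discovery_qc.n_snps,
            n_significant_snps=n_sig,
            discovery=rep_d,
            validation=rep_v,
            power=power,
            checksums=checksums,
        )

        if config.out_dir:
            stage = "write"
            os.makedirs(config.out_dir, exist_ok=True)
            with open(os.path.join(config.out_dir, "report.json"), "w") as fh:
                fh.write(report.to_json())
            qc_report_frame(records).to_csv(
                os.path.join(config.out_dir, "qc_report.tsv"), sep="\t", index=False
            )
            assoc_frame(assoc).to_csv(
                os.path.join(config.out_dir, "association.tsv"), sep="\t", index=False
            )
            weights.table.to_csv(
                os.path.join(config.out_dir, "weights.tsv"), sep="\t", index=False
            )
        return report
    except Exception as exc:
        raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc
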