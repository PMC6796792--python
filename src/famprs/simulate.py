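"""Ascertained nuclear-family cohort simulation.

Families are generated founder-first: parental genotypes are drawn in
Hardy-Weinberg proportions at each SNP, offspring genotypes by Mendelian
transmission (each parent passes the counted allele with probability g/2).
BMI is additive on the natural scale,

    BMI = mu + b_sex (male - 1/2) + b_age (age - mean age) + s + e

with s the true polygenic score (genotypes times per-allele effects, centred)
and Gaussian noise e scaled so that s carries ``h2_score`` of the BMI variance
in the unascertained population. Ascertainment follows the recruitment rule of
family studies of obesity — keep a family only if at least one parent AND at
least one offspring are at or above the ascertainment threshold — and is
implemented by rejection sampling of whole families, which is exact.

Recruitment happens years before the cross-sectional measurement, so the rule
is applied to a recruitment-time BMI = measured BMI + Gaussian drift of SD
``recruitment_bmi_noise_sd``. Without that drift a 2-parent/~2-offspring family
satisfying the rule would contain at least two currently obese members and the
cohort prevalence could never fall to the ~28% such studies report; the drift
term reproduces the regression-to-the-mean that makes those prevalences real.
Setting ``recruitment_bmi_noise_sd=0`` applies the rule to measured BMI exactly.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .cohort import (
    FEMALE,
    MALE,
    FamilyCohort,
    ParameterError,
    Pedigree,
    SimulationConfig,
    _offspring_spec,
)

__all__ = [
    "simulate_cohort",
    "ascertain_families",
    "split_cohort",
    "calibrate_base_mean",
    "age_moments",
]


def age_moments(config: SimulationConfig) -> tuple[float, float]:
    """Mean and variance of age under the parent/offspring sampling mixture."""
    lo_p, hi_p = config.parent_age_range
    lo_o, hi_o = config.offspring_age_range
    _, _, mean_off = _offspring_spec(config.offspring_per_family)
    w_par = 2.0 / (2.0 + mean_off)
    m_p, v_p = 0.5 * (lo_p + hi_p), (hi_p - lo_p) ** 2 / 12.0
    m_o, v_o = 0.5 * (lo_o + hi_o), (hi_o - lo_o) ** 2 / 12.0
    mean = w_par * m_p + (1 - w_par) * m_o
    var = w_par * (v_p + m_p**2) + (1 - w_par) * (v_o + m_o**2) - mean**2
    return mean, var


def _snp_panel(config: SimulationConfig, rng: np.random.Generator):
    """Per-SNP MAFs, counted-allele effects on BMI, and imputation metadata."""
    m = config.n_snps
    lo, hi = config.maf_range
    maf = rng.uniform(lo, hi, size=m)
    if config.effect_sizes is not None:
        effects = np.asarray(config.effect_sizes, dtype=float)
    elif config.h2_score == 0.0:
        effects = np.zeros(m)
    else:
        raw = rng.normal(size=m)
        var_raw = np.sum(raw**2 * 2.0 * maf * (1.0 - maf))
        target = config.h2_score * config.bmi_base_sd**2
        effects = raw * np.sqrt(target / var_raw)
    imputed = rng.random(m) < config.fraction_imputed
    r2 = np.full(m, np.nan)
    r2[imputed] = rng.uniform(*config.imputation_r2_range, size=imputed.sum())
    alleles = np.array(["A", "C", "G", "T"])
    a1 = rng.integers(0, 4, size=m)
    a2 = (a1 + rng.integers(1, 4, size=m)) % 4
    meta = pd.DataFrame(
        {
            "snp_id": [f"snp{j + 1:04d}" for j in range(m)],
            "counted_allele": alleles[a1],
            "other_allele": alleles[a2],
            "maf": maf,
            "effect": effects,
            "imputation_r2": r2,
        }
    )
    return maf, effects, meta


def _noise_sd(config: SimulationConfig, var_score: float) -> float:
    _, var_age = age_moments(config)
    var_env = (
        config.bmi_base_sd**2
        - var_score
        - 0.25 * config.sex_effect**2
        - var_age * config.age_effect**2
    )
    if var_env <= 0:
        raise ParameterError(
            "bmi_base_sd too small for the requested score and covariate effects"
        )
    return float(np.sqrt(var_env))


def _draw_family(
    rng: np.random.Generator,
    maf: np.ndarray,
    effects: np.ndarray,
    score_mean: float,
    noise_sd: float,
    age_mean: float,
    config: SimulationConfig,
):
    lo, hi, mean_off = _offspring_spec(config.offspring_per_family)
    k = lo if hi == lo else lo + rng.binomial(hi - lo, (mean_off - lo) / (hi - lo))
    n = 2 + k
    geno = np.empty((n, len(maf)))
    geno[0] = rng.binomial(2, maf)
    geno[1] = rng.binomial(2, maf)
    for c in range(k):
        geno[2 + c] = rng.binomial(1, geno[0] / 2.0) + rng.binomial(1, geno[1] / 2.0)
    sex = np.concatenate([[MALE, FEMALE], rng.integers(0, 2, size=k) * 1 + 1])
    age = np.concatenate(
        [
            rng.uniform(*config.parent_age_range, size=2),
            rng.uniform(*config.offspring_age_range, size=k),
        ]
    )
    score = geno @ effects - score_mean
    bmi = (
        config.bmi_base_mean
        + config.sex_effect * ((sex == MALE) - 0.5)
        + config.age_effect * (age - age_mean)
        + score
        + rng.normal(0.0, noise_sd, size=n)
    )
    recruit_bmi = bmi
    if config.recruitment_bmi_noise_sd > 0:
        recruit_bmi = bmi + rng.normal(0.0, config.recruitment_bmi_noise_sd, size=n)
    return geno, sex, age, score, bmi, recruit_bmi, k


def simulate_cohort(config: SimulationConfig, ascertain: bool = True) -> FamilyCohort:
    """Generate a nuclear-family cohort under the configured model.

    With ``ascertain=True`` (default) whole families are rejection-sampled
    until ``n_families`` satisfy the recruitment rule (>=1 parent and >=1
    offspring with BMI >= ``ascertainment_bmi``); with ``ascertain=False``
    the first ``n_families`` simulated families are kept regardless of BMI,
    giving an unascertained population sample.
    """
    rng = np.random.default_rng(config.seed)
    maf, effects, meta = _snp_panel(config, rng)
    score_mean = float(effects @ (2.0 * maf))
    var_score = float(np.sum(effects**2 * 2.0 * maf * (1.0 - maf)))
    noise_sd = _noise_sd(config, var_score)
    age_mean, _ = age_moments(config)

    rows, genos, scores = [], [], []
    phen_rows = []
    kept = 0
    attempts = 0
    max_attempts = max(2000, 5000 * config.n_families)
    while kept < config.n_families:
        attempts += 1
        if attempts > max_attempts:
            raise ParameterError(
                "ascertainment rejection sampling exceeded the attempt budget; "
                "the configured BMI model makes the recruitment rule too rare"
            )
        geno, sex, age, score, bmi, recruit_bmi, k = _draw_family(
            rng, maf, effects, score_mean, noise_sd, age_mean, config
        )
        if ascertain and config.ascertainment_bmi is not None:
            if not (
                recruit_bmi[:2].max() >= config.ascertainment_bmi
                and recruit_bmi[2:].max(initial=-np.inf) >= config.ascertainment_bmi
            ):
                continue
        kept += 1
        fid = f"F{kept:04d}"
        iids = [f"{fid}_P1", f"{fid}_P2"] + [f"{fid}_O{c + 1}" for c in range(k)]
        fathers = ["", ""] + [iids[0]] * k
        mothers = ["", ""] + [iids[1]] * k
        for i in range(2 + k):
            rows.append((fid, iids[i], fathers[i], mothers[i], int(sex[i])))
            phen_rows.append((iids[i], float(bmi[i]), int(sex[i]), float(age[i])))
        genos.append(geno)
        scores.append(score)

    ped = Pedigree(pd.DataFrame(rows, columns=["fid", "iid", "father", "mother", "sex"]))
    genotypes = np.vstack(genos)
    if config.missing_rate > 0:
        mask = rng.random(genotypes.shape) < config.missing_rate
        genotypes = genotypes.astype(float)
        genotypes[mask] = np.nan
    phen = pd.DataFrame(phen_rows, columns=["iid", "bmi", "sex", "age"])
    phen["obesity"] = (phen["bmi"] >= config.obesity_threshold).astype(int)
    return FamilyCohort(
        pedigree=ped,
        genotypes=genotypes,
        snp_meta=meta,
        phenotypes=phen[["iid", "bmi", "obesity", "sex", "age"]],
        true_score=np.concatenate(scores),
        obesity_threshold=config.obesity_threshold,
    )


def ascertain_families(cohort: FamilyCohort, threshold: float) -> FamilyCohort:
    """Keep families with >=1 parent AND >=1 offspring at/above the BMI threshold.

    Parents are the pedigree founders of each family. An empty cohort (or one
    where no family qualifies) yields an empty result, not an error.
    """
    bmi = cohort.bmi
    founder = cohort.pedigree.is_founder
    keep: list[np.ndarray] = []
    for _, idx in cohort.families().items():
        par = idx[founder[idx]]
        off = idx[~founder[idx]]
        if len(par) and len(off) and bmi[par].max() >= threshold and bmi[off].max() >= threshold:
            keep.append(idx)
    if not keep:
        return cohort.subset_individuals(np.asarray([], dtype=int))
    return cohort.subset_individuals(np.concatenate(keep))


def _stratified_counts(sizes: np.ndarray, fraction: float, n_first: int) -> np.ndarray:
    base = np.floor(fraction * sizes).astype(int)
    deficit = n_first - base.sum()
    frac = fraction * sizes - base
    order = np.argsort(-frac, kind="stable")
    take = base.copy()
    for g in order[: max(deficit, 0)]:
        take[g] += 1
    return take


def split_cohort(
    cohort: FamilyCohort,
    fraction: float,
    seed: int,
    stratify_by_obesity: bool = True,
    by_family: bool = False,
) -> tuple[FamilyCohort, FamilyCohort]:
    """Random partition into (discovery, validation) with |discovery| = floor(fraction*n).

    With ``stratify_by_obesity`` the obese and non-obese strata are allocated
    proportionally (largest-remainder rounding), so partition prevalences
    differ by at most one count. ``by_family`` keeps whole families together
    instead, in which case the discovery size is the closest achievable with
    intact families.
    """
    if not (0.0 < fraction < 1.0):
        raise ParameterError("fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    n = cohort.n_individuals
    n_first = int(np.floor(fraction * n))

    if by_family:
        fams = list(cohort.families().values())
        order = rng.permutation(len(fams))
        first: list[np.ndarray] = []
        count = 0
        for fi in order:
            if count >= n_first:
                break
            first.append(fams[fi])
            count += len(fams[fi])
        chosen = np.concatenate(first) if first else np.asarray([], dtype=int)
    elif stratify_by_obesity:
        ob = cohort.obesity
        groups = [np.flatnonzero(ob == 1), np.flatnonzero(ob == 0)]
        sizes = np.array([len(g) for g in groups])
        take = _stratified_counts(sizes, fraction, n_first)
        chosen = np.concatenate(
            [rng.permutation(g)[:k] for g, k in zip(groups, take)]
        )
    else:
        chosen = rng.permutation(n)[:n_first]

    mask = np.zeros(n, dtype=bool)
    mask[chosen] = True
    first_idx = np.flatnonzero(mask)
    second_idx = np.flatnonzero(~mask)
    return cohort.subset_individuals(first_idx), cohort.subset_individuals(second_idx)


def calibrate_base_mean(
    config: SimulationConfig,
    target_prevalence: float = 0.28,
    seed: int | None = None,
    n_families: int = 300,
    tol: float = 0.004,
    max_iter: int = 25,
) -> float:
    """Bisection on the BMI intercept so that post-ascertainment obesity
    prevalence approximates ``target_prevalence``.

    Each bisection step simulates ``n_families`` ascertained families at a
    fixed evaluation seed, so the calibration is deterministic.
    """
    if not (0.0 < target_prevalence < 1.0):
        raise ParameterError("target_prevalence must be in (0, 1)")
    eval_seed = config.seed if seed is None else seed

    def prevalence(mu: float) -> float:
        c = config.replace(bmi_base_mean=mu, n_families=n_families, seed=eval_seed)
        cohort = simulate_cohort(c, ascertain=True)
        return float(cohort.obesity.mean())

    # Bracket around the obesity threshold: far below it the ascertainment rule
    # becomes so rare that rejection sampling is impractical.
    lo = config.obesity_threshold - 1.8 * config.bmi_base_sd
    hi = config.obesity_threshold + 0.5 * config.bmi_base_sd
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        p = prevalence(mid)
        if abs(p - target_prevalence) < tol:
            return mid
        if p < target_prevalence:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)
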