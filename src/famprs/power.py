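"""Analytic power of a polygenic score trained in one sample and tested in another.

The model follows the classical polygenic-score power framework (training
sample estimates per-SNP effects with sampling error; the estimated score is
then tested for association in an independent target sample):

* Each of ``n_snps`` markers is standardised; per-SNP effect estimates carry
  sampling error of variance 1/n_train, so the estimated score accumulates
  error variance ``n_snps / n_train``.
* ``score_r2_train`` is the proportion of phenotypic variance on the
  quantitative/liability scale that the estimated score explains in the
  training population. Inverting the error model gives the implied variance
  ``vg`` carried by the true marker effects.
* For a binary trait the phenotype is a liability threshold at the sample
  prevalence K; correlations between a liability-scale predictor and the
  observed 0/1 trait attenuate by c(K) = phi(t)/sqrt(K(1-K)), t = Phi^-1(1-K).
* The expected squared score-trait correlation in the target is then
  ``rho2 = score_r2_train * c(K_target)^2`` (binary) or ``score_r2_train``
  (quantitative); the association test has noncentrality
  ``ncp = n_target * rho2 / (1 - rho2)`` on one chi-square df, and
  power = P(chi2_1(ncp) > chi2_1 quantile at 1 - alpha).

:func:`mc_power` verifies the closed form by simulating the full
train-estimate-score-test cycle under the same generative model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import chi2, ncx2, norm

from .cohort import ParameterError

__all__ = ["PowerInputs", "PowerResult", "MCPowerResult", "analytic_power", "mc_power"]


@dataclass(frozen=True)
class PowerInputs:
    n_train: int
    n_target: int
    prevalence_train: float = 0.5
    prevalence_target: float = 0.5
    n_snps: int = 1
    score_r2_train: float = 0.0
    pi_null: float = 0.0  # fraction of effect-free SNPs (Monte-Carlo only; see note)
    alpha: float = 0.05
    trait: str = "binary"  # "binary" (liability threshold) or "quantitative"

    def __post_init__(self) -> None:
        if self.n_train < 1 or self.n_target < 1:
            raise ParameterError("sample sizes must be >= 1")
        if self.n_snps < 1:
            raise ParameterError("n_snps must be >= 1")
        for name in ("prevalence_train", "prevalence_target"):
            v = getattr(self, name)
            if not (0.0 < v < 1.0):
                raise ParameterError(f"{name} must be in (0, 1)")
        if not (0.0 <= self.score_r2_train < 1.0):
            raise ParameterError("score_r2_train must be in [0, 1)")
        if not (0.0 <= self.pi_null <= 1.0):
            raise ParameterError("pi_null must be in [0, 1]")
        if not (0.0 < self.alpha <= 1.0):
            raise ParameterError("alpha must be in (0, 1]")
        if self.trait not in ("binary", "quantitative"):
            raise ParameterError("trait must be 'binary' or 'quantitative'")


@dataclass(frozen=True)
class PowerResult:
    rho2_target: float  # expected squared score-trait correlation in the target
    ncp: float
    power: float
    implied_vg: float  # liability-scale variance carried by the true marker effects


def _attenuation_sq(prevalence: float) -> float:
    t = norm.ppf(1.0 - prevalence)
    z = norm.pdf(t)
    return float(z * z / (prevalence * (1.0 - prevalence)))


def _implied_vg(inputs: PowerInputs) -> float:
    """Underlying marker variance solving r2 = vg^2 c1^2 / (vg c1^2 + m/n1)."""
    r2 = inputs.score_r2_train
    if r2 == 0.0:
        return 0.0
    c1sq = _attenuation_sq(inputs.prevalence_train) if inputs.trait == "binary" else 1.0
    err = inputs.n_snps / inputs.n_train
    # c1^2 vg^2 - r2 c1^2 vg - r2 err = 0
    disc = (r2 * c1sq) ** 2 + 4.0 * c1sq * r2 * err
    vg = (r2 * c1sq + np.sqrt(disc)) / (2.0 * c1sq)
    if vg >= 1.0:
        raise ParameterError(
            "infeasible inputs: implied genetic variance >= 1 "
            f"(vg = {vg:.3f}); reduce score_r2_train or increase n_train"
        )
    return float(vg)


def analytic_power(inputs: PowerInputs) -> PowerResult:
    """Closed-form power of the score-trait association test in the target."""
    vg = _implied_vg(inputs)
    c2sq = _attenuation_sq(inputs.prevalence_target) if inputs.trait == "binary" else 1.0
    rho2 = inputs.score_r2_train * c2sq
    if rho2 >= 1.0:
        raise ParameterError("expected target correlation is >= 1; infeasible inputs")
    ncp = inputs.n_target * rho2 / (1.0 - rho2)
    crit = chi2.ppf(1.0 - inputs.alpha, 1)
    power = float(ncx2.sf(crit, 1, ncp)) if ncp > 0 else float(inputs.alpha)
    return PowerResult(rho2_target=float(rho2), ncp=float(ncp), power=power, implied_vg=vg)


@dataclass(frozen=True)
class MCPowerResult:
    power: float
    se: float
    reps: int


def _corr_cols_with(y: np.ndarray, g: np.ndarray) -> np.ndarray:
    """Pearson correlation of each column of g (reps, n, m) with y (reps, n)."""
    yc = y - y.mean(axis=1, keepdims=True)
    gc = g - g.mean(axis=1, keepdims=True)
    num = np.einsum("rn,rnm->rm", yc, gc)
    den = np.sqrt(np.einsum("rn,rn->r", yc, yc))[:, None] * np.sqrt(
        np.einsum("rnm,rnm->rm", gc, gc)
    )
    with np.errstate(invalid="ignore", divide="ignore"):
        out = num / den
    return np.nan_to_num(out)


def mc_power(inputs: PowerInputs, reps: int, seed: int = 0) -> MCPowerResult:
    """Monte-Carlo power: simulate training, estimate per-SNP weights by
    marginal correlation, score the target sample, test at level alpha.

    Standardised Gaussian genotypes are used — the power model operates on
    correlations, for which allele-count genotypes are equivalent at these
    sample sizes. ``pi_null`` sets the fraction of SNPs simulated with zero
    effect (the true variance concentrates on the rest)."""
    if reps < 1:
        raise ParameterError("reps must be >= 1")
    vg = _implied_vg(inputs)
    m = inputs.n_snps
    n1, n2 = inputs.n_train, inputs.n_target
    n_eff = max(1, int(round((1.0 - inputs.pi_null) * m))) if vg > 0 else 0
    b = np.zeros(m)
    if n_eff:
        b[:n_eff] = np.sqrt(vg / n_eff)
    t1 = norm.ppf(1.0 - inputs.prevalence_train)
    t2 = norm.ppf(1.0 - inputs.prevalence_target)
    crit = chi2.ppf(1.0 - inputs.alpha, 1)
    rng = np.random.default_rng(seed)
    noise_sd = np.sqrt(1.0 - vg)

    rejected = 0
    done = 0
    chunk = max(1, min(reps, int(2e7 // (max(n1, n2) * m) + 1)))
    while done < reps:
        r = min(chunk, reps - done)
        g1 = rng.standard_normal((r, n1, m))
        liab1 = g1 @ b + noise_sd * rng.standard_normal((r, n1))
        y1 = (liab1 > t1).astype(float) if inputs.trait == "binary" else liab1
        w = _corr_cols_with(y1, g1)  # (r, m) estimated weights
        g2 = rng.standard_normal((r, n2, m))
        liab2 = g2 @ b + noise_sd * rng.standard_normal((r, n2))
        y2 = (liab2 > t2).astype(float) if inputs.trait == "binary" else liab2
        score = np.einsum("rnm,rm->rn", g2, w)
        rr = _corr_cols_with(y2, score[:, :, None])[:, 0]
        stat = n2 * rr**2 / np.clip(1.0 - rr**2, 1e-12, None)
        rejected += int((stat > crit).sum())
        done += r
    p = rejected / reps
    return MCPowerResult(power=float(p), se=float(np.sqrt(p * (1 - p) / reps)), reps=reps)
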