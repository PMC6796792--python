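"""Stratification metrics for a polygenic score against obesity.

Covers the score-obesity association (trend odds ratio per score unit,
quintile odds ratios vs the lowest quintile), discrimination
(rank-based AUC, Harrell-style optimism-corrected AUC with bias-corrected
bootstrap comparison intervals), reclassification (continuous NRI, IDI) and
the share of BMI variance the score explains under a kinship linear mixed
model.

Predicted probabilities are population-level (random effect at zero):
expit(X beta-hat) from the logistic mixed fit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit
from scipy.stats import norm, rankdata

from .cohort import MALE, ParameterError
from .mixedmodels import (
    RandomEffectStructure,
    fit_lmm,
    fit_logistic_mixed,
)
from .prs import QUINTILE_LABELS

__all__ = [
    "TrendResult",
    "QuintileOR",
    "AUCReport",
    "NRIIDIReport",
    "VarianceExplained",
    "trend_test",
    "quintile_or_test",
    "auc",
    "optimism_bootstrap",
    "nri_idi",
    "variance_explained",
]


def _male_indicator(sex: np.ndarray) -> np.ndarray:
    sex = np.asarray(sex)
    vals = set(np.unique(sex).tolist())
    if vals <= {0, 1}:
        return sex.astype(float)
    return (sex == MALE).astype(float)


# ---------------------------------------------------------------------------
# trend and quintile odds ratios


@dataclass
class TrendResult:
    odds_ratio: float  # per score unit (or per SD with per_sd=True)
    ci_low: float
    ci_high: float
    p: float
    beta: float
    se: float
    per_sd: bool
    sigma_g2: float
    model: str = "obesity ~ sex + age + PRS, random = kinship"


def trend_test(
    prs: np.ndarray,
    obesity: np.ndarray,
    sex: np.ndarray,
    age: np.ndarray,
    structure: RandomEffectStructure,
    per_sd: bool = False,
) -> TrendResult:
    """Wald linear-trend test on the continuous score's coefficient.

    The default scale is per score unit; ``per_sd=True`` rescales to one
    sample standard deviation of the score (OR_sd = OR_unit ** sd)."""
    prs = np.asarray(prs, dtype=float)
    x = np.column_stack([np.ones_like(prs), _male_indicator(sex), np.asarray(age, float), prs])
    fit = fit_logistic_mixed(np.asarray(obesity, float), x, structure)
    beta, se = float(fit.beta[-1]), float(fit.se[-1])
    scale = float(prs.std(ddof=1)) if per_sd else 1.0
    b, s = beta * scale, se * scale
    return TrendResult(
        odds_ratio=float(np.exp(b)),
        ci_low=float(np.exp(b - 1.959963984540054 * s)),
        ci_high=float(np.exp(b + 1.959963984540054 * s)),
        p=fit.wald_p(-1),
        beta=b,
        se=s,
        per_sd=per_sd,
        sigma_g2=fit.sigma_g2,
    )


@dataclass
class QuintileOR:
    quintile: str
    odds_ratio: float
    ci_low: float
    ci_high: float
    p: float
    estimable: bool
    n_cases: int
    n_total: int


def quintile_or_test(
    quintiles: np.ndarray,
    obesity: np.ndarray,
    sex: np.ndarray,
    age: np.ndarray,
    structure: RandomEffectStructure,
) -> list[QuintileOR]:
    """Odds ratio of each upper quintile vs Q1, from one logistic mixed model
    with the quintile entered as four indicator contrasts.

    Q1 is returned with OR fixed at 1. A quintile whose cases (or controls)
    are absent is flagged non-estimable; the remaining contrasts are still
    reported."""
    quintiles = np.asarray(quintiles)
    y = np.asarray(obesity, dtype=float)
    if not ((y == 1).any() and (y == 0).any()):
        raise ParameterError("need at least one case and one control")
    indicators = [(quintiles == q).astype(float) for q in QUINTILE_LABELS[1:]]
    x = np.column_stack(
        [np.ones(len(y)), _male_indicator(sex), np.asarray(age, float), *indicators]
    )
    import warnings as _warnings

    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore", RuntimeWarning)
        fit = fit_logistic_mixed(y, x, structure)
    out = [
        QuintileOR("Q1", 1.0, np.nan, np.nan, np.nan, True,
                   int(y[quintiles == "Q1"].sum()), int((quintiles == "Q1").sum()))
    ]
    for k, q in enumerate(QUINTILE_LABELS[1:]):
        j = 3 + k
        b, s = float(fit.beta[j]), float(fit.se[j])
        in_q = quintiles == q
        n_cases = int(y[in_q].sum())
        estimable = 0 < n_cases < int(in_q.sum()) and abs(b) <= 20.0
        out.append(
            QuintileOR(
                quintile=q,
                odds_ratio=float(np.exp(min(b, 700.0))),
                ci_low=float(np.exp(min(b - 1.959963984540054 * s, 700.0))),
                ci_high=float(np.exp(min(b + 1.959963984540054 * s, 700.0))),
                p=fit.wald_p(j),
                estimable=estimable,
                n_cases=n_cases,
                n_total=int(in_q.sum()),
            )
        )
    return out


# ---------------------------------------------------------------------------
# discrimination


def auc(pred: np.ndarray, y: np.ndarray) -> float:
    """Rank-based (Mann-Whitney) AUC; tied predictions count one half."""
    pred = np.asarray(pred, dtype=float)
    y = np.asarray(y)
    n1 = int((y == 1).sum())
    n0 = int((y == 0).sum())
    if n1 == 0 or n0 == 0:
        raise ParameterError("AUC requires both classes")
    ranks = rankdata(pred)  # average ranks on ties
    return float((ranks[y == 1].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0))


@dataclass
class AUCReport:
    apparent: float
    optimism: float
    auc_adj: float
    B: int
    seed: int | None = None
    # present when two model specs were compared
    apparent_base: float | None = None
    auc_adj_base: float | None = None
    delta_adj: float | None = None
    ci_diff: tuple[float, float] | None = None
    significant: bool | None = None


def _fit_predict(y, x, structure):
    fit = fit_logistic_mixed(y, x, structure)
    return fit, expit(np.clip(x @ fit.beta, -30, 30))


def _bc_interval(draws: np.ndarray, point: float, level: float = 0.95) -> tuple[float, float]:
    """Bias-corrected (no acceleration) percentile interval."""
    z_alpha = norm.ppf(0.5 + level / 2.0)
    frac = np.clip(np.mean(draws < point), 1.0 / (len(draws) + 1), 1.0 - 1.0 / (len(draws) + 1))
    z0 = norm.ppf(frac)
    lo = norm.cdf(2 * z0 - z_alpha)
    hi = norm.cdf(2 * z0 + z_alpha)
    return float(np.quantile(draws, lo)), float(np.quantile(draws, hi))


def optimism_bootstrap(
    y: np.ndarray,
    x: np.ndarray,
    structure: RandomEffectStructure,
    B: int = 1000,
    seed: int = 0,
    x_base: np.ndarray | None = None,
    family_ids: np.ndarray | None = None,
) -> AUCReport:
    """Optimism-corrected AUC of the logistic mixed model with design ``x``.

    Harrell's procedure: for each of B resamples, refit on the resample and
    record optimism_b = AUC(resample fit on resample) - AUC(resample fit on
    the original data); AUC_adj = apparent - mean optimism. B = 0 returns
    the apparent AUC uncorrected.

    With ``x_base`` the same resamples evaluate a second (nested/base) model
    and the report carries the optimism-corrected AUC difference
    ``delta_adj`` (x-model minus base) with a bias-corrected percentile 95%
    interval of the paired corrected differences; ``significant`` is True
    when that interval excludes zero.

    Resampling is by individual; pass ``family_ids`` to resample whole
    families instead (the safer choice under family correlation).
    """
    import warnings as _warnings

    y = np.asarray(y, dtype=float)
    rng = np.random.default_rng(seed)
    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore", RuntimeWarning)
        _, pred = _fit_predict(y, x, structure)
        apparent = auc(pred, y)
        apparent_base = None
        if x_base is not None:
            _, pred_b = _fit_predict(y, x_base, structure)
            apparent_base = auc(pred_b, y)
        if B == 0:
            return AUCReport(apparent, 0.0, apparent, 0, seed,
                             apparent_base, apparent_base,
                             None if x_base is None else apparent - apparent_base,
                             None, None)

        if family_ids is not None:
            fids = np.asarray(family_ids)
            fam_index = {}
            for i, f in enumerate(fids):
                fam_index.setdefault(f, []).append(i)
            fam_members = [np.asarray(v) for v in fam_index.values()]

        a = structure.a
        opt1 = np.empty(B)
        opt2 = np.empty(B) if x_base is not None else None
        b_done = 0
        attempts = 0
        while b_done < B and attempts < 10 * B + 100:
            attempts += 1
            if family_ids is not None:
                pick = rng.integers(0, len(fam_members), size=len(fam_members))
                idx = np.concatenate([fam_members[k] for k in pick])
            else:
                idx = rng.integers(0, len(y), size=len(y))
            yb = y[idx]
            if yb.min() == yb.max():
                continue  # resample lost a class; redraw
            sb = RandomEffectStructure(a[np.ix_(idx, idx)])
            try:
                fit_b, pred_in = _fit_predict(yb, x[idx], sb)
            except np.linalg.LinAlgError:
                continue
            pred_out = expit(np.clip(x @ fit_b.beta, -30, 30))
            opt1[b_done] = auc(pred_in, yb) - auc(pred_out, y)
            if x_base is not None:
                fit_b2, pred_in2 = _fit_predict(yb, x_base[idx], sb)
                pred_out2 = expit(np.clip(x_base @ fit_b2.beta, -30, 30))
                opt2[b_done] = auc(pred_in2, yb) - auc(pred_out2, y)
            b_done += 1
        if b_done < B:
            raise ParameterError("too many degenerate bootstrap resamples")

    auc_adj = apparent - float(opt1.mean())
    if x_base is None:
        return AUCReport(apparent, float(opt1.mean()), auc_adj, B, seed)
    auc_adj_base = apparent_base - float(opt2.mean())
    delta = auc_adj - auc_adj_base
    d_b = (apparent - opt1) - (apparent_base - opt2)
    ci = _bc_interval(d_b, delta)
    return AUCReport(
        apparent=apparent,
        optimism=float(opt1.mean()),
        auc_adj=auc_adj,
        B=B,
        seed=seed,
        apparent_base=apparent_base,
        auc_adj_base=auc_adj_base,
        delta_adj=delta,
        ci_diff=ci,
        significant=bool(ci[0] > 0 or ci[1] < 0),
    )


# ---------------------------------------------------------------------------
# reclassification


@dataclass
class NRIIDIReport:
    nri: float
    nri_ci: tuple[float, float]
    nri_p: float
    idi: float
    idi_ci: tuple[float, float]
    idi_p: float
    event_up: float
    event_down: float
    nonevent_up: float
    nonevent_down: float
    B: int = 0


def _nri_idi_point(p_old, p_new, y):
    ev, ne = y == 1, y == 0
    up, down = p_new > p_old, p_new < p_old
    eu = float(up[ev].mean())
    ed = float(down[ev].mean())
    nu = float(up[ne].mean())
    nd = float(down[ne].mean())
    nri = (eu - ed) + (nd - nu)
    idi = float((p_new[ev].mean() - p_old[ev].mean()) - (p_new[ne].mean() - p_old[ne].mean()))
    return nri, idi, eu, ed, nu, nd


def nri_idi(
    p_old: np.ndarray,
    p_new: np.ndarray,
    y: np.ndarray,
    B: int = 1000,
    seed: int = 0,
) -> NRIIDIReport:
    """Category-free net reclassification improvement and integrated
    discrimination improvement of risks ``p_new`` over ``p_old``.

    NRI = [P(up|event) - P(down|event)] + [P(down|nonevent) - P(up|nonevent)]
    with up/down meaning the new risk is higher/lower than the old; IDI is
    the change in mean risk separation between events and nonevents.
    Confidence intervals are percentile bootstrap over individuals; p-values
    are normal-theory on the bootstrap standard error. ``B=0`` skips the
    uncertainty estimates.
    """
    p_old = np.asarray(p_old, dtype=float)
    p_new = np.asarray(p_new, dtype=float)
    y = np.asarray(y)
    if ((p_old < 0) | (p_old > 1) | (p_new < 0) | (p_new > 1)).any():
        raise ParameterError("risks must lie in [0, 1]")
    if not ((y == 1).any() and (y == 0).any()):
        raise ParameterError("need both events and nonevents")
    nri, idi, eu, ed, nu, nd = _nri_idi_point(p_old, p_new, y)
    if B == 0:
        return NRIIDIReport(nri, (np.nan, np.nan), np.nan, idi, (np.nan, np.nan), np.nan,
                            eu, ed, nu, nd, 0)
    rng = np.random.default_rng(seed)
    draws = np.empty((B, 2))
    b = 0
    attempts = 0
    n = len(y)
    while b < B and attempts < 10 * B + 100:
        attempts += 1
        idx = rng.integers(0, n, size=n)
        yb = y[idx]
        if not ((yb == 1).any() and (yb == 0).any()):
            continue
        nri_b, idi_b, *_ = _nri_idi_point(p_old[idx], p_new[idx], yb)
        draws[b] = (nri_b, idi_b)
        b += 1
    if b < B:
        raise ParameterError("too many degenerate bootstrap resamples")
    ci_nri = tuple(np.quantile(draws[:, 0], [0.025, 0.975]))
    ci_idi = tuple(np.quantile(draws[:, 1], [0.025, 0.975]))
    se_nri = float(draws[:, 0].std(ddof=1))
    se_idi = float(draws[:, 1].std(ddof=1))
    p_nri = float(2 * norm.sf(abs(nri) / se_nri)) if se_nri > 0 else (1.0 if nri == 0 else 0.0)
    p_idi = float(2 * norm.sf(abs(idi) / se_idi)) if se_idi > 0 else (1.0 if idi == 0 else 0.0)
    return NRIIDIReport(
        nri, (float(ci_nri[0]), float(ci_nri[1])), p_nri,
        idi, (float(ci_idi[0]), float(ci_idi[1])), p_idi,
        eu, ed, nu, nd, B,
    )


# ---------------------------------------------------------------------------
# variance explained


@dataclass
class VarianceExplained:
    r2: float  # share of total BMI variance attributable to the score
    r2_partial: float  # squared partial correlation, for comparison
    beta_prs: float
    se_prs: float
    p: float
    sigma_g2_full: float
    sigma_e2_full: float
    model: str = "BMI ~ sex + age + PRS, random = kinship"


def variance_explained(
    bmi: np.ndarray,
    prs: np.ndarray,
    sex: np.ndarray,
    age: np.ndarray,
    structure: RandomEffectStructure,
) -> VarianceExplained:
    """Proportion of BMI variance explained by the score under the kinship
    linear mixed model.

    Primary definition: the drop in total model variance (genetic + residual
    REML components) when the score enters the fixed effects, as a fraction
    of the total sample BMI variance. The squared partial correlation of BMI
    and score given sex and age is reported alongside.
    """
    bmi = np.asarray(bmi, dtype=float)
    prs = np.asarray(prs, dtype=float)
    base = np.column_stack([np.ones_like(bmi), _male_indicator(sex), np.asarray(age, float)])
    full_x = np.column_stack([base, prs])
    fit_full = fit_lmm(bmi, full_x, structure)
    fit_red = fit_lmm(bmi, base, structure)
    total_var = float(bmi.var(ddof=1))
    r2 = max(0.0, (fit_red.total_variance - fit_full.total_variance) / total_var)
    # squared partial correlation on OLS residuals
    h = np.linalg.lstsq(base, np.column_stack([bmi, prs]), rcond=None)[0]
    resid = np.column_stack([bmi, prs]) - base @ h
    denom = resid[:, 0].std() * resid[:, 1].std()
    r2_partial = float((np.mean(resid[:, 0] * resid[:, 1]) / denom) ** 2) if denom > 0 else 0.0
    z = fit_full.beta[-1] / fit_full.se[-1]
    return VarianceExplained(
        r2=float(min(r2, 1.0)),
        r2_partial=r2_partial,
        beta_prs=float(fit_full.beta[-1]),
        se_prs=float(fit_full.se[-1]),
        p=float(2 * norm.sf(abs(z))),
        sigma_g2_full=fit_full.sigma_g2,
        sigma_e2_full=fit_full.sigma_e2,
    )
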