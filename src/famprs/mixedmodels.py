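"""Mixed models with a pedigree-structured random effect.

Two solvers share one covariance representation:

* :func:`fit_lmm` — linear mixed model ``y = X b + u + e`` with
  ``u ~ N(0, sigma_g^2 A)`` and iid noise, fitted by REML. The relationship
  matrix ``A`` (= 2 * kinship) is block-diagonal across families, so each
  block is eigendecomposed once and the REML criterion is a fast scalar
  optimisation over the variance ratio.

* :func:`fit_logistic_mixed` — logistic mixed model for a binary trait,
  fitted by penalised quasi-likelihood (PQL): iterate a working linearisation
  of the Bernoulli likelihood, estimate ``sigma_g^2`` by REML on the working
  variates (whose residual covariance is the inverse weight matrix), and
  solve the mixed-model equations for fixed effects and BLUPs. PQL is the
  method family of the classical family-GWAS tooling; its known downward
  bias for binary traits with large variance components is documented in the
  methods note.

Fixed-effect inference is Wald: se from (X' V^-1 X)^-1, two-sided normal
p-values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.special import expit

from .cohort import ParameterError

__all__ = [
    "DegenerateOutcomeError",
    "RandomEffectStructure",
    "LMMFit",
    "GLMMFit",
    "fit_lmm",
    "fit_logistic_mixed",
]

_SEPARATION_BETA = 20.0


class DegenerateOutcomeError(ValueError):
    """Binary outcome with a single class."""


def _connected_blocks(a: np.ndarray) -> list[np.ndarray]:
    from scipy.sparse import csr_matrix
    from scipy.sparse.csgraph import connected_components

    adj = csr_matrix(a != 0.0)
    n_comp, labels = connected_components(adj, directed=False)
    return [np.flatnonzero(labels == c) for c in range(n_comp)]


class RandomEffectStructure:
    """Block-diagonal relationship matrix with precomputed per-block pieces.

    Blocks are taken from ``family_ids`` when given, otherwise discovered as
    connected components of the nonzero pattern of ``a`` (unrelated
    individuals become singleton blocks). Cross-block entries of ``a`` must
    be zero.
    """

    def __init__(self, a: np.ndarray, family_ids: np.ndarray | None = None):
        a = np.asarray(a, dtype=float)
        n = a.shape[0]
        if a.shape != (n, n):
            raise ParameterError("relationship matrix must be square")
        if not np.allclose(a, a.T, atol=1e-10):
            raise ParameterError("relationship matrix must be symmetric")
        self.a = a
        self.n = n
        if family_ids is not None:
            fids = np.asarray(family_ids)
            order: dict = {}
            for i, f in enumerate(fids):
                order.setdefault(f, []).append(i)
            self.blocks = [np.asarray(ix) for ix in order.values()]
        else:
            self.blocks = _connected_blocks(a)
        # group blocks by size for stacked linear algebra
        self._groups: list[tuple[np.ndarray, np.ndarray]] = []
        by_size: dict[int, list[np.ndarray]] = {}
        for b in self.blocks:
            by_size.setdefault(len(b), []).append(b)
        for size, blks in sorted(by_size.items()):
            idx = np.vstack(blks)  # (k, size)
            a_stack = a[idx[:, :, None], idx[:, None, :]]  # (k, size, size)
            self._groups.append((idx, a_stack))
        self._eigen: tuple[np.ndarray, list[tuple[np.ndarray, np.ndarray]]] | None = None

    @classmethod
    def identity(cls, n: int) -> "RandomEffectStructure":
        return cls(np.eye(n))

    # -- eigendecomposition (homoscedastic LMM path) ---------------------
    def eigen(self):
        """Per-group eigendecompositions; returns (eigvals concatenated in
        group order, list of (idx, U_stack)). Transformed vectors follow the
        ordering produced by :meth:`transform`."""
        if self._eigen is None:
            d_parts = []
            transforms = []
            for idx, a_stack in self._groups:
                w, u = np.linalg.eigh(a_stack)  # (k, b), (k, b, b)
                d_parts.append(w.reshape(-1))
                transforms.append((idx, u))
            self._eigen = (np.concatenate(d_parts), transforms)
        return self._eigen

    def transform(self, m: np.ndarray) -> np.ndarray:
        """Apply the blockwise rotation U^T to a vector or column matrix."""
        d, transforms = self.eigen()
        vec = m.ndim == 1
        cols = m[:, None] if vec else m
        out_parts = []
        for idx, u in transforms:
            sub = cols[idx]  # (k, b, p)
            out_parts.append(np.einsum("kba,kbp->kap", u, sub).reshape(-1, cols.shape[1]))
        out = np.concatenate(out_parts, axis=0)
        return out[:, 0] if vec else out


@dataclass
class LMMFit:
    beta: np.ndarray
    se: np.ndarray
    sigma_g2: float
    sigma_e2: float
    reml: float  # -0.5 * restricted deviance (up to a constant)
    converged: bool
    names: list[str] | None = None

    @property
    def total_variance(self) -> float:
        return self.sigma_g2 + self.sigma_e2


@dataclass
class GLMMFit:
    beta: np.ndarray
    se: np.ndarray
    sigma_g2: float
    quasi_loglik: float
    converged: bool
    n_iterations: int
    separation: bool
    names: list[str] | None = None

    def wald_p(self, j: int) -> float:
        from scipy.stats import norm

        return float(2.0 * norm.sf(abs(self.beta[j] / self.se[j])))


def _check_design(y: np.ndarray, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    y = np.asarray(y, dtype=float).ravel()
    x = np.asarray(x, dtype=float)
    if x.ndim != 2 or x.shape[0] != y.size:
        raise ParameterError("X must be n x p with n matching y")
    if np.linalg.matrix_rank(x) < x.shape[1]:
        raise ParameterError("covariate matrix is rank deficient")
    return y, x


def fit_lmm(y: np.ndarray, x: np.ndarray, structure: RandomEffectStructure) -> LMMFit:
    """REML fit of the homoscedastic linear mixed model.

    The variance ratio lambda = sigma_g^2 / sigma_e^2 is profiled on the
    eigenbasis of the (block-diagonal) relationship matrix, with the residual
    variance solved in closed form at each candidate ratio.
    """
    y, x = _check_design(y, x)
    n, p = x.shape
    d, _ = structure.eigen()
    yt = structure.transform(y)
    xt = structure.transform(x)

    def reml_neg(lam: float) -> tuple[float, np.ndarray, float, np.ndarray]:
        w = 1.0 / (1.0 + lam * d)
        xtw = xt * w[:, None]
        xtwx = xt.T @ xtw
        beta = np.linalg.solve(xtwx, xtw.T @ yt)
        r = yt - xt @ beta
        rss = float(np.sum(w * r * r))
        sig_e2 = rss / (n - p)
        crit = (
            (n - p) * np.log(sig_e2)
            + np.sum(np.log1p(lam * d))
            + np.linalg.slogdet(xtwx)[1]
        )
        return crit, beta, sig_e2, xtwx

    def obj(t: float) -> float:
        return reml_neg(np.exp(t))[0]

    res = minimize_scalar(obj, bounds=(-12.0, 8.0), method="bounded", options={"xatol": 1e-6})
    lam = float(np.exp(res.x))
    crit0 = reml_neg(0.0)[0]
    if crit0 <= res.fun:
        lam = 0.0
    crit, beta, sig_e2, xtwx = reml_neg(lam)
    cov = sig_e2 * np.linalg.inv(xtwx)
    return LMMFit(
        beta=beta,
        se=np.sqrt(np.diag(cov)),
        sigma_g2=lam * sig_e2,
        sigma_e2=sig_e2,
        reml=-0.5 * crit,
        converged=bool(res.success),
    )


def _working_reml(
    structure: RandomEffectStructure,
    w: np.ndarray,
    z: np.ndarray,
    x: np.ndarray,
    s2: float,
):
    """REML pieces for the working model z = X b + u + e, Var(e) = diag(1/w),
    Var(u) = s2 * A. Returns (criterion, beta, cov_beta, u_blup)."""
    p = x.shape[1]
    logdet = 0.0
    xtvix = np.zeros((p, p))
    xtviz = np.zeros(p)
    ztviz = 0.0
    sols = []
    for idx, a_stack in structure._groups:
        k, b = idx.shape
        v = s2 * a_stack + np.einsum("kb,bc->kbc", 1.0 / w[idx], np.eye(b))
        cho = np.linalg.cholesky(v)
        logdet += 2.0 * float(np.log(np.einsum("kbb->kb", cho)).sum())
        rhs = np.concatenate([x[idx], z[idx][:, :, None]], axis=2)  # (k, b, p+1)
        sol = np.linalg.solve(v, rhs)
        xs, zs = sol[:, :, :p], sol[:, :, p]
        xtvix += np.einsum("kbp,kbq->pq", x[idx], xs)
        xtviz += np.einsum("kbp,kb->p", x[idx], zs)
        ztviz += float(np.einsum("kb,kb->", z[idx], zs))
        sols.append((idx, a_stack, v))
    beta = np.linalg.solve(xtvix, xtviz)
    quad = ztviz - float(xtviz @ beta)
    crit = logdet + np.linalg.slogdet(xtvix)[1] + quad
    # BLUP u = s2 * A V^-1 (z - X beta), blockwise
    u = np.zeros(x.shape[0])
    r = z - x @ beta
    for idx, a_stack, v in sols:
        rv = np.linalg.solve(v, r[idx][:, :, None])[:, :, 0]
        u[idx] = s2 * np.einsum("kbc,kc->kb", a_stack, rv)
    return crit, beta, np.linalg.inv(xtvix), u


def _plain_irls(y: np.ndarray, x: np.ndarray, max_iter: int = 30) -> np.ndarray:
    beta = np.zeros(x.shape[1])
    beta[0] = np.log(y.mean() / (1.0 - y.mean()))
    for _ in range(max_iter):
        eta = x @ beta
        mu = expit(eta)
        w = np.clip(mu * (1.0 - mu), 1e-8, None)
        z = eta + (y - mu) / w
        xw = x * w[:, None]
        new = np.linalg.solve(xw.T @ x + 1e-10 * np.eye(x.shape[1]), xw.T @ z)
        new = np.clip(new, -30.0, 30.0)
        if np.max(np.abs(new - beta)) < 1e-8:
            beta = new
            break
        beta = new
    return beta


def fit_logistic_mixed(
    y: np.ndarray,
    x: np.ndarray,
    structure: RandomEffectStructure | np.ndarray,
    max_iter: int = 100,
    tol: float = 1e-6,
    names: list[str] | None = None,
) -> GLMMFit:
    """PQL fit of a logistic mixed model with relationship covariance.

    ``structure`` is a :class:`RandomEffectStructure` (or a raw relationship
    matrix, from which one is built). Raises
    :class:`DegenerateOutcomeError` when the outcome has a single class; sets
    ``separation=True`` (with a warning) when any fixed effect exceeds 20 in
    absolute value, returning the estimate regardless.
    """
    y, x = _check_design(y, x)
    if len(np.unique(y)) < 2:
        raise DegenerateOutcomeError("binary outcome has a single class")
    if not np.isin(y, (0.0, 1.0)).all():
        raise ParameterError("outcome must be binary 0/1")
    if not isinstance(structure, RandomEffectStructure):
        structure = RandomEffectStructure(np.asarray(structure))
    if structure.n != y.size:
        raise ParameterError("relationship structure size must match y")

    beta = _plain_irls(y, x)
    u = np.zeros(y.size)
    s2 = 0.1
    converged = False
    n_iter = 0
    cov = np.eye(x.shape[1])
    crit = np.inf
    for n_iter in range(1, max_iter + 1):
        eta = np.clip(x @ beta + u, -30.0, 30.0)
        mu = expit(eta)
        w = np.clip(mu * (1.0 - mu), 1e-6, None)
        z = eta + (y - mu) / w

        def obj(t: float) -> float:
            return _working_reml(structure, w, z, x, float(np.exp(t)))[0]

        res = minimize_scalar(obj, bounds=(-18.0, 4.0), method="bounded", options={"xatol": 1e-4})
        s2_new = float(np.exp(res.x))
        if obj(-18.0) <= res.fun:
            s2_new = 0.0
        crit, beta_new, cov, u = _working_reml(structure, w, z, x, s2_new)
        delta = max(np.max(np.abs(beta_new - beta)), abs(s2_new - s2))
        beta, s2 = beta_new, s2_new
        if delta < tol:
            converged = True
            break

    separation = bool(np.max(np.abs(beta)) > _SEPARATION_BETA)
    if separation:
        warnings.warn("possible separation: |beta| > 20", RuntimeWarning, stacklevel=2)
    return GLMMFit(
        beta=beta,
        se=np.sqrt(np.diag(cov)),
        sigma_g2=s2,
        quasi_loglik=-0.5 * crit,
        converged=converged,
        n_iterations=n_iter,
        separation=separation,
        names=names,
    )
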