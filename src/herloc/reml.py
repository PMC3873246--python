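"""Average-Information REML for variance-component heritability models.

The phenotype model is y = Xb + sum_c g_c + e with g_c ~ N(0, sigma2_c A_c)
and e ~ N(0, sigma2_e I).  Fixed effects are projected out of the
likelihood (restricted ML).  Each iteration takes an AI quasi-Newton step
on the variance components, falling back to a single EM step whenever the
AI step leaves the feasible region or fails to improve the restricted
log-likelihood; components that go negative are clamped to a small positive
floor.  The inverse of the final Average Information matrix provides the
covariance of the component estimates, from which heritability standard
errors follow by the delta method.

A single-GRM fit is solved in the eigenbasis of the GRM (one O(n^3)
decomposition, then O(n p^2) per iteration); multi-component fits use the
generic dense path.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg, stats

_CLAMP_FRACTION = 1e-6


class NonIdentifiableError(ValueError):
    """Two relatedness matrices in the model are (numerically) identical."""


class NotPositiveDefiniteError(ValueError):
    """The phenotypic covariance V failed to be positive definite."""


@dataclass
class VCFit:
    """Result of a variance-component fit.

    sigma2 holds the genetic components followed by the residual; h2 is the
    per-component share of total variance, h2_total their sum.  Standard
    errors are analytical (AI-matrix based).  ai_inverse is the covariance
    matrix of all components (genetic + residual) in trait-variance units.
    """

    sigma2: np.ndarray
    se_sigma2: np.ndarray
    h2: np.ndarray
    se_h2: np.ndarray
    h2_total: float
    se_h2_total: float
    ai_inverse: np.ndarray
    loglik: float
    n_iter: int
    converged: bool
    clamped: np.ndarray

    @property
    def sigma2_e(self) -> float:
        return float(self.sigma2[-1])


def _as_matrix(g) -> np.ndarray:
    return np.asarray(g.A if hasattr(g, "A") else g, dtype=float)


class _DenseModel:
    """Generic REML working quantities for any number of components."""

    def __init__(self, y, x, mats):
        self.y = y
        self.x = x
        self.mats = mats  # includes trailing identity
        self.n, self.p = x.shape

    def quantities(self, theta):
        n = self.n
        v = sum(t * a for t, a in zip(theta, self.mats))
        jitter = 0.0
        for _ in range(3):
            try:
                cf = linalg.cho_factor(v + jitter * np.eye(n), lower=True)
                break
            except linalg.LinAlgError:
                jitter = max(jitter * 10, 1e-8 * np.trace(v) / n)
        else:
            raise NotPositiveDefiniteError("V is not positive definite")
        vinv_x = linalg.cho_solve(cf, self.x)
        vinv_y = linalg.cho_solve(cf, self.y)
        b = self.x.T @ vinv_x
        b_cf = linalg.cho_factor(b)
        py = vinv_y - vinv_x @ linalg.cho_solve(b_cf, self.x.T @ vinv_y)
        logdet_v = 2.0 * np.sum(np.log(np.diag(cf[0])))
        logdet_b = 2.0 * np.sum(np.log(np.diag(b_cf[0])))
        loglik = -0.5 * (logdet_v + logdet_b + float(self.y @ py))

        k = len(self.mats)
        apy, papy, tr_pa = [], [], np.empty(k)
        for i, a in enumerate(self.mats):
            apy_i = a @ py
            vinv_apy = linalg.cho_solve(cf, apy_i)
            papy_i = vinv_apy - vinv_x @ linalg.cho_solve(b_cf, self.x.T @ vinv_apy)
            vinv_a = linalg.cho_solve(cf, a)
            tr_pa[i] = np.trace(vinv_a) - np.trace(
                linalg.cho_solve(b_cf, vinv_x.T @ a @ vinv_x)
            )
            apy.append(apy_i)
            papy.append(papy_i)
        ypapy = np.array([float(py @ a) for a in apy])
        ai = 0.5 * np.array(
            [[float(apy[i] @ papy[j]) for j in range(k)] for i in range(k)]
        )
        ai = 0.5 * (ai + ai.T)
        grad = -0.5 * (tr_pa - ypapy)
        return loglik, grad, ai, ypapy, tr_pa


class _EigenModel:
    """Single-GRM model solved in the GRM eigenbasis."""

    def __init__(self, y, x, a):
        lam, u = np.linalg.eigh(a)
        self.lam = np.clip(lam, 0.0, None)
        self.yt = u.T @ y
        self.xt = u.T @ x
        self.n, self.p = x.shape

    def quantities(self, theta):
        diags = [self.lam, np.ones(self.n)]
        d = theta[0] * self.lam + theta[1]
        if np.min(d) <= 0:
            raise NotPositiveDefiniteError("V is not positive definite")
        dinv = 1.0 / d
        xt, yt = self.xt, self.yt
        b = xt.T @ (dinv[:, None] * xt)
        b_cf = linalg.cho_factor(b)
        alpha = linalg.cho_solve(b_cf, xt.T @ (dinv * yt))
        py = dinv * (yt - xt @ alpha)
        logdet_v = float(np.sum(np.log(d)))
        logdet_b = 2.0 * np.sum(np.log(np.diag(b_cf[0])))
        loglik = -0.5 * (logdet_v + logdet_b + float(yt @ py))

        apy, papy, tr_pa = [], [], np.empty(2)
        for i, a_diag in enumerate(diags):
            apy_i = a_diag * py
            dinv_apy = dinv * apy_i
            papy_i = dinv_apy - dinv * (
                xt @ linalg.cho_solve(b_cf, xt.T @ dinv_apy)
            )
            m = xt.T @ ((dinv * dinv * a_diag)[:, None] * xt)
            tr_pa[i] = float(np.sum(a_diag * dinv)) - float(
                np.trace(linalg.cho_solve(b_cf, m))
            )
            apy.append(apy_i)
            papy.append(papy_i)
        ypapy = np.array([float(py @ a) for a in apy])
        ai = 0.5 * np.array(
            [[float(apy[i] @ papy[j]) for j in range(2)] for i in range(2)]
        )
        ai = 0.5 * (ai + ai.T)
        grad = -0.5 * (tr_pa - ypapy)
        return loglik, grad, ai, ypapy, tr_pa


def _check_identifiable(mats):
    k = len(mats)
    for i in range(k):
        for j in range(i + 1, k):
            if np.allclose(mats[i], mats[j], atol=1e-10):
                raise NonIdentifiableError(
                    f"components {i} and {j} have identical covariance structures"
                )


def ai_reml(
    y,
    fixed_effects,
    grms,
    max_iter: int = 100,
    tol_loglik: float = 1e-4,
    tol_param: float = 1e-6,
) -> VCFit:
    """Fit V = sum_c sigma2_c A_c + sigma2_e I by AI-REML.

    Parameters
    ----------
    y : (n,) phenotype (no missing values).
    fixed_effects : (n, p) full-column-rank design; pass a column of ones
        for an intercept-only model.
    grms : list of GRM objects (or raw symmetric matrices), one per genetic
        component.  The residual identity component is implicit.

    Convergence requires both |Delta loglik| < ``tol_loglik`` and maximum
    relative parameter change < ``tol_param``.
    """
    y = np.asarray(y, dtype=float)
    x = np.atleast_2d(np.asarray(fixed_effects, dtype=float))
    if x.shape[0] != y.shape[0]:
        x = x.T
    n = y.shape[0]
    if np.linalg.matrix_rank(x) < x.shape[1]:
        raise ValueError("fixed_effects design is rank deficient")
    mats = [_as_matrix(g) for g in grms]
    for a in mats:
        if a.shape != (n, n):
            raise ValueError("GRM dimensions do not match the phenotype")
    _check_identifiable(mats + [np.eye(n)])

    k = len(mats)
    vary = float(np.var(y))
    if vary <= 0:
        raise ValueError("phenotype has zero variance")
    floor = _CLAMP_FRACTION * vary
    theta = np.full(k + 1, vary / (k + 1))

    model = _EigenModel(y, x, mats[0]) if k == 1 else _DenseModel(y, x, mats + [np.eye(n)])

    loglik, grad, ai, ypapy, tr_pa = model.quantities(theta)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        # proposed AI-Newton step; components driven negative are pinned at
        # the floor and dropped from the Newton system (active-set handling)
        step_ok = True
        active = (theta > floor * (1 + 1e-9)) | (grad > 0)
        try:
            delta = np.zeros(k + 1)
            if active.any():
                ia = np.flatnonzero(active)
                delta[ia] = np.linalg.solve(ai[np.ix_(ia, ia)], grad[ia])
            theta_new = np.maximum(theta + delta, floor)
        except np.linalg.LinAlgError:
            step_ok = False
            theta_new = None
        if step_ok:
            try:
                out = model.quantities(theta_new)
            except NotPositiveDefiniteError:
                step_ok = False
            else:
                if out[0] < loglik - tol_loglik:
                    step_ok = False
        if not step_ok:
            # EM step: always feasible, monotone in the likelihood
            theta_new = theta + theta**2 * (ypapy - tr_pa) / n
            theta_new = np.maximum(theta_new, floor)
            out = model.quantities(theta_new)

        new_loglik = out[0]
        rel_change = np.max(np.abs(theta_new - theta) / np.maximum(np.abs(theta), floor))
        dll = abs(new_loglik - loglik)
        theta, (loglik, grad, ai, ypapy, tr_pa) = theta_new, out
        if dll < tol_loglik and rel_change < tol_param:
            converged = True
            break

    clamped = theta <= floor * (1 + 1e-12)
    theta = np.maximum(theta, floor)

    try:
        ai_inv = np.linalg.inv(ai)
    except np.linalg.LinAlgError:
        ai_inv = np.linalg.pinv(ai)
    se_sigma2 = np.sqrt(np.clip(np.diag(ai_inv), 0.0, None))

    total = float(theta.sum())
    h2 = theta[:k] / total
    se_h2 = np.empty(k)
    for c in range(k):
        g = -theta[c] / total**2 * np.ones(k + 1)
        g[c] += 1.0 / total
        se_h2[c] = np.sqrt(max(float(g @ ai_inv @ g), 0.0))
    gen = float(theta[:k].sum())
    g_tot = -gen / total**2 * np.ones(k + 1)
    g_tot[:k] += 1.0 / total
    se_h2_total = np.sqrt(max(float(g_tot @ ai_inv @ g_tot), 0.0))

    return VCFit(
        sigma2=theta,
        se_sigma2=se_sigma2,
        h2=h2,
        se_h2=se_h2,
        h2_total=gen / total,
        se_h2_total=se_h2_total,
        ai_inverse=ai_inv,
        loglik=float(loglik),
        n_iter=it,
        converged=converged,
        clamped=clamped,
    )


def reml_loglik(theta, y, fixed_effects, grms) -> float:
    """Restricted log-likelihood at fixed components (for grids/diagnostics)."""
    y = np.asarray(y, dtype=float)
    x = np.asarray(fixed_effects, dtype=float)
    mats = [_as_matrix(g) for g in grms] + [np.eye(len(y))]
    model = _DenseModel(y, x, mats)
    return model.quantities(np.asarray(theta, dtype=float))[0]


def liability_transform(h2_obs, se_obs, prevalence_k, sample_p):
    """Observed-scale to liability-scale heritability for ascertained traits.

    h2_liab = h2_obs * K^2 (1-K)^2 / (z^2 P (1-P)) with z the standard
    normal density at the threshold truncating the upper K of liability.
    The map is linear, so standard errors scale by the same factor and any
    ratio or z-score built from transformed estimates is unchanged.
    """
    k, p = float(prevalence_k), float(sample_p)
    if not (0.0 < k < 1.0) or not (0.0 < p < 1.0):
        raise ValueError("prevalence K and sample case fraction P must be in (0,1)")
    z = stats.norm.pdf(stats.norm.isf(k))
    factor = k**2 * (1.0 - k) ** 2 / (z**2 * p * (1.0 - p))
    return h2_obs * factor, se_obs * factor


def ztest_increase(h2_est, se_est, expected):
    """One-sided upper-tail Z-test of an estimate against its expectation.

    Returns (gain, z, p) with gain = h2_est / expected.  Noise on the
    expectation is deliberately not modeled: the estimate and its
    expectation derive from the same SNPs and samples, so the models are
    partially nested rather than independent.
    """
    gain = h2_est / expected
    z = (h2_est - expected) / se_est
    p = stats.norm.sf(z)
    return gain, z, p
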