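"""Maximum-likelihood logistic mixed models.

Frequentist ML fitting of logistic random-effects models is implemented
here directly (the surrounding ecosystem offers Bayesian/variational
approximations, which are kept as cross-checks in the test-suite, not used
as the estimator):

* scalar random intercept — marginal likelihood integrated by *adaptive*
  Gauss-Hermite quadrature (nodes recentred at the per-group conditional
  mode and rescaled by the conditional curvature), 21 nodes by default;
* vector-valued random effects (one intercept per condition, unstructured
  covariance) — Laplace approximation, the standard approach for
  multidimensional integrals where tensor-product quadrature is
  impractical.

Both return the ML estimates, observed-information standard errors,
empirical-Bayes conditional modes, and the exact quantities AIC/BIC are
recomputed from.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.polynomial.hermite_e import hermegauss
from scipy import optimize

__all__ = ["LogisticGLMMResult", "fit_logistic_intercept", "fit_logistic_vector"]

_SIGMOID_CLIP = 30.0


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -_SIGMOID_CLIP, _SIGMOID_CLIP)))


def _log1pexp(x: np.ndarray) -> np.ndarray:
    # log(1 + exp(x)), stable
    out = np.where(x > 0, x, 0.0) + np.log1p(np.exp(-np.abs(x)))
    return out


@dataclass
class LogisticGLMMResult:
    beta: np.ndarray            # fixed effects
    beta_se: np.ndarray
    cov_re: np.ndarray          # random-effect covariance (q x q)
    llf: float                  # maximized marginal log-likelihood
    n_params: int               # free parameters (beta + covariance)
    nobs: int
    n_groups: int
    ranef_modes: np.ndarray     # (n_groups, q) empirical-Bayes conditional modes
    converged: bool
    singular: bool              # covariance estimate on/near the boundary
    optimizer_message: str


def _group_slices(groups: np.ndarray) -> list[np.ndarray]:
    uniq, inv = np.unique(groups, return_inverse=True)
    return [np.where(inv == g)[0] for g in range(len(uniq))]


# ---------------------------------------------------------------------------
# scalar random intercept, adaptive Gauss-Hermite
# ---------------------------------------------------------------------------

def _group_loglik_aghq(eta_fix: np.ndarray, y: np.ndarray, sigma: float,
                       nodes: np.ndarray, weights: np.ndarray) -> tuple[float, float]:
    """Marginal log-likelihood contribution of one group and its mode."""
    # conditional mode of b via Newton on f(b) = sum loglik + log N(b;0,sigma^2)
    b = 0.0
    for _ in range(50):
        eta = eta_fix + b
        mu = _sigmoid(eta)
        grad = float(np.sum(y - mu)) - b / sigma**2
        hess = -float(np.sum(mu * (1 - mu))) - 1.0 / sigma**2
        step = grad / hess
        b -= step
        if abs(step) < 1e-10:
            break
    eta = eta_fix + b
    mu = _sigmoid(eta)
    curv = float(np.sum(mu * (1 - mu))) + 1.0 / sigma**2  # -f''(b̂)
    tau = 1.0 / np.sqrt(curv)
    # adaptive nodes: b_k = b̂ + tau * z_k, Gauss-Hermite (probabilists')
    bk = b + tau * nodes
    etak = eta_fix[:, None] + bk[None, :]
    ll_cond = np.sum(y[:, None] * etak - _log1pexp(etak), axis=0)
    log_prior = -0.5 * np.log(2 * np.pi) - np.log(sigma) - 0.5 * (bk / sigma) ** 2
    # integral ≈ tau * sum_k w_k exp(f(b_k) + z_k^2/2), weights include exp(-z^2/2)
    log_terms = ll_cond + log_prior + 0.5 * nodes**2 + np.log(weights) + np.log(tau)
    m = log_terms.max()
    return m + np.log(np.sum(np.exp(log_terms - m))), b


def fit_logistic_intercept(
    y: np.ndarray,
    X: np.ndarray,
    groups: np.ndarray,
    n_quad: int = 21,
) -> LogisticGLMMResult:
    """ML logistic regression with a per-group random intercept.

    The random-intercept standard deviation is parameterised on the log
    scale; standard errors of the fixed effects come from the numerically
    differentiated observed information of the profile in all parameters.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    slices = _group_slices(np.asarray(groups))
    nodes, weights = hermegauss(n_quad)
    p = X.shape[1]

    def negll(theta: np.ndarray) -> float:
        beta, log_sigma = theta[:p], theta[p]
        sigma = np.exp(log_sigma)
        eta = X @ beta
        total = 0.0
        for idx in slices:
            ll, _ = _group_loglik_aghq(eta[idx], y[idx], sigma, nodes, weights)
            total += ll
        return -total

    # start from the no-random-effect logistic fit
    from scipy.optimize import minimize
    beta0 = _plain_logistic(y, X)
    theta0 = np.concatenate([beta0, [np.log(0.5)]])
    res = minimize(negll, theta0, method="BFGS",
                   options={"gtol": 1e-6, "maxiter": 500})
    beta = res.x[:p]
    sigma = float(np.exp(res.x[p]))
    hess = _numeric_hessian(negll, res.x)
    se = _se_from_hessian(hess)[:p]
    eta = X @ beta
    modes = np.array([
        _group_loglik_aghq(eta[idx], y[idx], sigma, nodes, weights)[1]
        for idx in slices
    ])
    singular = sigma < 1e-4
    return LogisticGLMMResult(
        beta=beta, beta_se=se, cov_re=np.array([[sigma**2]]),
        llf=-res.fun, n_params=p + 1, nobs=len(y), n_groups=len(slices),
        ranef_modes=modes[:, None], converged=bool(res.success or res.status == 2),
        singular=singular, optimizer_message=str(res.message),
    )


def _plain_logistic(y: np.ndarray, X: np.ndarray) -> np.ndarray:
    beta = np.zeros(X.shape[1])
    for _ in range(50):  # IRLS
        mu = _sigmoid(X @ beta)
        w = np.clip(mu * (1 - mu), 1e-10, None)
        z = X @ beta + (y - mu) / w
        beta_new = np.linalg.lstsq(X * np.sqrt(w)[:, None],
                                   z * np.sqrt(w), rcond=None)[0]
        if np.max(np.abs(beta_new - beta)) < 1e-10:
            beta = beta_new
            break
        beta = beta_new
    return beta


def _numeric_hessian(f, x: np.ndarray, eps: float = 1e-4) -> np.ndarray:
    n = len(x)
    H = np.zeros((n, n))
    f0 = f(x)
    for i in range(n):
        for j in range(i, n):
            xpp = x.copy(); xpp[i] += eps; xpp[j] += eps
            xpm = x.copy(); xpm[i] += eps; xpm[j] -= eps
            xmp = x.copy(); xmp[i] -= eps; xmp[j] += eps
            xmm = x.copy(); xmm[i] -= eps; xmm[j] -= eps
            H[i, j] = H[j, i] = (f(xpp) - f(xpm) - f(xmp) + f(xmm)) / (4 * eps**2)
    return H


def _se_from_hessian(hess: np.ndarray) -> np.ndarray:
    try:
        cov = np.linalg.inv(hess)
        d = np.diag(cov).copy()
        d[d < 0] = np.nan
        return np.sqrt(d)
    except np.linalg.LinAlgError:
        return np.full(hess.shape[0], np.nan)


# ---------------------------------------------------------------------------
# vector-valued random effects, Laplace approximation
# ---------------------------------------------------------------------------

def _group_loglik_laplace(
    eta_fix: np.ndarray, y: np.ndarray, Z: np.ndarray, prec: np.ndarray,
    logdet_cov: float,
) -> tuple[float, np.ndarray]:
    """Laplace-approximate marginal log-likelihood of one group.

    ``prec`` is the inverse random-effect covariance; ``Z`` the group's
    random-effect design.
    """
    q = Z.shape[1]
    b = np.zeros(q)
    for _ in range(100):
        eta = eta_fix + Z @ b
        mu = _sigmoid(eta)
        grad = Z.T @ (y - mu) - prec @ b
        W = mu * (1 - mu)
        H = (Z.T * W) @ Z + prec
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(H, grad, rcond=None)[0]
        b += step
        if np.max(np.abs(step)) < 1e-10:
            break
    eta = eta_fix + Z @ b
    mu = _sigmoid(eta)
    ll_cond = float(np.sum(y * eta - _log1pexp(eta)))
    log_prior = -0.5 * (q * np.log(2 * np.pi) + logdet_cov + b @ prec @ b)
    W = mu * (1 - mu)
    H = (Z.T * W) @ Z + prec
    sign, logdet_H = np.linalg.slogdet(H)
    ll = ll_cond + log_prior + 0.5 * q * np.log(2 * np.pi) - 0.5 * logdet_H
    return ll, b


def _chol_from_theta(theta: np.ndarray, q: int) -> np.ndarray:
    """Lower-triangular Cholesky factor with log-parameterised diagonal."""
    L = np.zeros((q, q))
    k = 0
    for i in range(q):
        for j in range(i + 1):
            if i == j:
                L[i, j] = np.exp(theta[k])
            else:
                L[i, j] = theta[k]
            k += 1
    return L


def fit_logistic_vector(
    y: np.ndarray,
    X: np.ndarray,
    Z: np.ndarray,
    groups: np.ndarray,
    unstructured: bool = True,
) -> LogisticGLMMResult:
    """ML logistic regression with a q-dimensional per-group random effect.

    The covariance is parameterised by its Cholesky factor (log-diagonal),
    or by independent log-standard deviations when ``unstructured`` is
    False.  The marginal likelihood uses the Laplace approximation.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    Z = np.asarray(Z, dtype=float)
    slices = _group_slices(np.asarray(groups))
    p, q = X.shape[1], Z.shape[1]
    n_cov = q * (q + 1) // 2 if unstructured else q

    def cov_from_theta(tc: np.ndarray) -> np.ndarray:
        if unstructured:
            L = _chol_from_theta(tc, q)
        else:
            L = np.diag(np.exp(tc))
        return L @ L.T

    def negll(theta: np.ndarray) -> float:
        beta, tc = theta[:p], theta[p:]
        cov = cov_from_theta(tc)
        # guard against ill-conditioning during the search
        cov = cov + 1e-10 * np.eye(q)
        prec = np.linalg.inv(cov)
        sign, logdet = np.linalg.slogdet(cov)
        eta = X @ beta
        total = 0.0
        for idx in slices:
            ll, _ = _group_loglik_laplace(eta[idx], y[idx], Z[idx], prec, logdet)
            total += ll
        return -total

    beta0 = _plain_logistic(y, X)
    if unstructured:
        tc0 = np.zeros(n_cov)
        k = 0
        for i in range(q):
            for j in range(i + 1):
                tc0[k] = np.log(0.5) if i == j else 0.0
                k += 1
    else:
        tc0 = np.full(q, np.log(0.5))
    theta0 = np.concatenate([beta0, tc0])
    res = optimize.minimize(negll, theta0, method="BFGS",
                            options={"gtol": 1e-5, "maxiter": 1000})
    beta = res.x[:p]
    cov = cov_from_theta(res.x[p:])
    hess = _numeric_hessian(negll, res.x)
    se = _se_from_hessian(hess)[:p]
    prec = np.linalg.inv(cov + 1e-10 * np.eye(q))
    sign, logdet = np.linalg.slogdet(cov + 1e-10 * np.eye(q))
    eta = X @ beta
    modes = np.array([
        _group_loglik_laplace(eta[idx], y[idx], Z[idx], prec, logdet)[1]
        for idx in slices
    ])
    sd = np.sqrt(np.diag(cov))
    singular = bool(np.any(sd < 1e-4)) or np.linalg.cond(cov) > 1e8
    return LogisticGLMMResult(
        beta=beta, beta_se=se, cov_re=cov,
        llf=-res.fun, n_params=p + n_cov, nobs=len(y), n_groups=len(slices),
        ranef_modes=modes, converged=bool(res.success or res.status == 2),
        singular=singular, optimizer_message=str(res.message),
    )
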