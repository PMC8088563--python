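"""Maximum-likelihood logistic regression with a per-group random intercept.

Model: logit Pr(y=1 | u_j) = X beta + u_j, with u_j ~ Normal(0, sigma^2)
independent across groups. The marginal log-likelihood integrates the
random intercept out of each group's contribution; the integral is
evaluated by adaptive Gauss-Hermite quadrature centered at the per-group
posterior mode (found by Newton's method; the integrand is strictly
log-concave). sigma = 0 is a valid boundary value and reduces exactly to
ordinary logistic regression.

The quadrature accuracy contract is agreement with direct numerical
integration of the same marginal likelihood to ~1e-6 per observation on
small problems; the test suite enforces 1e-4 overall.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.optimize

_N_QUAD = 25
_GH_NODES, _GH_WEIGHTS = np.polynomial.hermite.hermgauss(_N_QUAD)


def _log_expit(eta: np.ndarray) -> np.ndarray:
    """log(1/(1+exp(-eta))) computed stably."""
    return -np.logaddexp(0.0, -eta)


def _cluster_modes(y, eta_fixed, gidx, n_groups, sigma2):
    """Newton solve for the posterior mode of each group's random intercept."""
    u = np.zeros(n_groups)
    for _ in range(50):
        eta = eta_fixed + u[gidx]
        p = 1.0 / (1.0 + np.exp(-np.clip(eta, -35, 35)))
        grad = np.bincount(gidx, weights=y - p, minlength=n_groups) - u / sigma2
        hess = np.bincount(gidx, weights=p * (1 - p), minlength=n_groups) + 1.0 / sigma2
        step = grad / hess
        u += step
        if np.max(np.abs(step)) < 1e-10:
            break
    eta = eta_fixed + u[gidx]
    p = 1.0 / (1.0 + np.exp(-np.clip(eta, -35, 35)))
    hess = np.bincount(gidx, weights=p * (1 - p), minlength=n_groups) + 1.0 / sigma2
    return u, hess


def mixed_logit_loglik(beta, sigma, y, X, gidx, n_groups) -> float:
    """Marginal log-likelihood at (beta, sigma) via adaptive Gauss-Hermite."""
    eta_fixed = X @ beta
    if sigma < 1e-10:
        ll = y * _log_expit(eta_fixed) + (1 - y) * _log_expit(-eta_fixed)
        return float(ll.sum())
    sigma2 = sigma * sigma
    u_hat, hess = _cluster_modes(y, eta_fixed, gidx, n_groups, sigma2)
    tau = 1.0 / np.sqrt(hess)  # curvature scale at the mode

    # h(u) = sum_k loglik_k(u) - u^2/(2 sigma^2) - log(sigma sqrt(2 pi))
    # integral ~= sqrt(2) tau sum_m w_m exp(h(u_hat + sqrt(2) tau t_m) + t_m^2)
    nodes = u_hat[:, None] + np.sqrt(2.0) * tau[:, None] * _GH_NODES[None, :]
    h = np.empty((n_groups, _N_QUAD))
    for m in range(_N_QUAD):
        eta = eta_fixed + nodes[:, m][gidx]
        ll_cells = y * _log_expit(eta) + (1 - y) * _log_expit(-eta)
        h[:, m] = np.bincount(gidx, weights=ll_cells, minlength=n_groups)
    h -= nodes**2 / (2.0 * sigma2)
    h -= np.log(sigma) + 0.5 * np.log(2.0 * np.pi)

    expo = h + _GH_NODES[None, :] ** 2 + np.log(_GH_WEIGHTS)[None, :]
    mx = expo.max(axis=1)
    log_int = mx + np.log(np.exp(expo - mx[:, None]).sum(axis=1))
    log_int += 0.5 * np.log(2.0) + np.log(tau)
    return float(log_int.sum())


@dataclass
class MixedLogitResult:
    params: np.ndarray       # fixed-effect coefficients
    sigma: float             # random-intercept standard deviation
    loglik: float
    converged: bool
    bse: np.ndarray | None   # standard errors of the fixed effects (on demand)


def _start_values(y, X):
    """Ridge-stabilized logistic start values (plain GLM, few IRLS steps)."""
    n, p = X.shape
    beta = np.zeros(p)
    for _ in range(25):
        eta = np.clip(X @ beta, -35, 35)
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = np.maximum(mu * (1 - mu), 1e-10)
        z = eta + (y - mu) / w
        xtwx = (X * w[:, None]).T @ X + 1e-8 * np.eye(p)
        beta_new = np.linalg.solve(xtwx, (X * w[:, None]).T @ z)
        if np.max(np.abs(beta_new - beta)) < 1e-8:
            beta = beta_new
            break
        beta = beta_new
    return np.clip(beta, -10, 10)


def fit_mixed_logit(y, X, groups, compute_bse: bool = False) -> MixedLogitResult:
    """Fit the random-intercept logistic model by marginal ML.

    groups may be any labels; they are factorized internally. The
    random-intercept SD is optimized on [0, 25]; a boundary estimate of 0
    is accepted (no boundary-corrected reference distribution is used).
    """
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != y.size:
        X = X.T
    _, gidx = np.unique(np.asarray(groups), return_inverse=True)
    n_groups = int(gidx.max()) + 1

    p = X.shape[1]
    beta0 = _start_values(y, X)

    def neg(theta):
        return -mixed_logit_loglik(theta[:p], theta[p], y, X, gidx, n_groups)

    best = None
    for sigma0 in (0.5, 1.5):
        x0 = np.concatenate([beta0, [sigma0]])
        res = scipy.optimize.minimize(
            neg, x0, method="L-BFGS-B",
            bounds=[(-30, 30)] * p + [(0.0, 25.0)],
            options={"maxiter": 200, "ftol": 1e-11},
        )
        if best is None or res.fun < best.fun:
            best = res
        if res.success:
            break
    theta = best.x
    ll = -best.fun
    bse = None
    if compute_bse:
        bse = _wald_bse(theta, y, X, gidx, n_groups, p)
    return MixedLogitResult(
        params=theta[:p], sigma=float(theta[p]), loglik=float(ll),
        converged=bool(best.success and np.isfinite(ll)), bse=bse,
    )


def _wald_bse(theta, y, X, gidx, n_groups, p):
    """Fixed-effect SEs from a finite-difference Hessian of the marginal loglik.

    When sigma sits at the 0 boundary the Hessian is taken over beta only.
    """
    sigma_at_zero = theta[p] < 1e-6
    k = p if sigma_at_zero else p + 1

    def f(v):
        th = theta.copy()
        th[:k] = v
        return -mixed_logit_loglik(th[:p], max(th[p], 0.0) if not sigma_at_zero else theta[p],
                                   y, X, gidx, n_groups)

    v0 = theta[:k].copy()
    h = 1e-4 * np.maximum(np.abs(v0), 1.0)
    H = np.empty((k, k))
    f0 = f(v0)
    for i in range(k):
        for j in range(i, k):
            vi, vj = v0.copy(), v0.copy()
            vij = v0.copy()
            vi[i] += h[i]
            vj[j] += h[j]
            vij[i] += h[i]
            vij[j] += h[j]
            H[i, j] = H[j, i] = (f(vij) - f(vi) - f(vj) + f0) / (h[i] * h[j])
    try:
        cov = np.linalg.inv(H)
        var = np.diag(cov)[:p]
        if np.any(var <= 0):
            return None
        return np.sqrt(var)
    except np.linalg.LinAlgError:
        return None
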