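"""Exact ML for the linear mixed model with one random intercept per group.

y = X beta + u_g + e, with u_g ~ N(0, tau^2), e ~ N(0, sigma^2). For a fixed
variance ratio theta = tau^2 / sigma^2 the GLS solution and the residual
variance are closed-form (Woodbury: V_g^{-1} = I - theta/(1 + theta n_g) J),
so the full ML reduces to a 1-D optimization of the profiled log-likelihood
over theta >= 0 — deterministic and robust at any group structure. A
boundary estimate theta = 0 (no between-group variance) is valid and
reduces to OLS.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.optimize


@dataclass
class MixedLMResult:
    params: np.ndarray     # fixed effects
    bse: np.ndarray        # their standard errors
    sigma2: float          # residual variance
    tau2: float            # random-intercept variance
    loglik: float
    converged: bool


def _profile_parts(theta: float, y, X, starts, counts):
    """GLS pieces at a given variance ratio; groups are contiguous blocks."""
    n, p = X.shape
    XtVX = np.zeros((p, p))
    XtVy = np.zeros(p)
    yty = 0.0
    logdet = 0.0
    for s, m in zip(starts, counts):
        sl = slice(s, s + m)
        Xg, yg = X[sl], y[sl]
        c = theta / (1.0 + theta * m)
        sx = Xg.sum(axis=0)
        sy = yg.sum()
        XtVX += Xg.T @ Xg - c * np.outer(sx, sx)
        XtVy += Xg.T @ yg - c * sx * sy
        yty += yg @ yg - c * sy * sy
        logdet += np.log1p(theta * m)
    beta = np.linalg.solve(XtVX, XtVy)
    rss = yty - beta @ XtVy  # r' V^-1 r at the GLS solution
    return beta, XtVX, max(rss, 1e-300), logdet


def _profile_nll(theta, y, X, starts, counts):
    n = y.size
    _, _, rss, logdet = _profile_parts(theta, y, X, starts, counts)
    sigma2 = rss / n
    return 0.5 * (n * (np.log(2.0 * np.pi * sigma2) + 1.0) + logdet)


def fit_mixed_lm(y, X, groups) -> MixedLMResult:
    """Maximum-likelihood fit; groups may be arbitrary labels."""
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != y.size:
        X = X.T
    order = np.argsort(np.asarray(groups), kind="stable")
    y = y[order]
    X = X[order]
    glab = np.asarray(groups)[order]
    change = np.flatnonzero(np.r_[True, glab[1:] != glab[:-1]])
    starts = change
    counts = np.diff(np.r_[change, glab.size])

    # bracket the optimum on a log-spaced grid, then refine with Brent
    grid = np.r_[0.0, np.logspace(-4, 3, 30)]
    vals = [_profile_nll(t, y, X, starts, counts) for t in grid]
    k = int(np.argmin(vals))
    lo = grid[max(k - 1, 0)]
    hi = grid[min(k + 1, grid.size - 1)]
    res = scipy.optimize.minimize_scalar(
        _profile_nll, bounds=(lo, max(hi, lo + 1e-8)), args=(y, X, starts, counts),
        method="bounded", options={"xatol": 1e-10},
    )
    theta = float(res.x)
    if _profile_nll(0.0, y, X, starts, counts) <= res.fun:
        theta = 0.0

    beta, XtVX, rss, _ = _profile_parts(theta, y, X, starts, counts)
    n = y.size
    sigma2 = rss / n
    cov = sigma2 * np.linalg.inv(XtVX)
    ll = -_profile_nll(theta, y, X, starts, counts)
    return MixedLMResult(
        params=beta,
        bse=np.sqrt(np.maximum(np.diag(cov), 0.0)),
        sigma2=float(sigma2),
        tau2=float(theta * sigma2),
        loglik=float(ll),
        converged=bool(np.isfinite(ll)),
    )
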