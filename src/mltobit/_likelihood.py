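"""Vectorised likelihood kernels for the random-intercept model.

Everything here works on plain arrays: ``y`` (outcome), ``X`` (design with
intercept), ``cidx`` (dense cluster codes 0..G-1) and scalar variance
components ``phi`` (between) and ``sigma2`` (within).  Per-cluster sums are
taken with ``np.bincount`` so no ordering of rows is assumed.

The uncensored marginal likelihood, its score and observed Hessian are
analytic.  The censored (Tobit) likelihood integrates the random intercept
by adaptive Gauss--Hermite quadrature: per cluster the integrand's mode is
found by a vectorised Newton iteration (the log-integrand is strictly
concave in u) and the standard Hermite rule is recentred and rescaled there.
"""

from __future__ import annotations

from typing import Optional, Tuple

import numpy as np
from numpy.polynomial.hermite import hermgauss
from scipy.special import log_ndtr

_LOG2PI = float(np.log(2.0 * np.pi))


def _csum(cidx: np.ndarray, G: int, values: np.ndarray) -> np.ndarray:
    return np.bincount(cidx, weights=values, minlength=G)


# ---------------------------------------------------------------------------
# Uncensored marginal likelihood (multivariate normal per cluster)
# ---------------------------------------------------------------------------


def mlm_cluster_logliks(
    y: np.ndarray,
    X: np.ndarray,
    cidx: np.ndarray,
    G: int,
    beta: np.ndarray,
    phi: float,
    sigma2: float,
) -> np.ndarray:
    """Per-cluster log N(y_j; X_j beta, sigma2*I + phi*J).

    Uses the closed-form determinant/inverse of the compound-symmetric
    covariance: eigenvalues sigma2 (n-1 times) and sigma2 + n*phi.
    """
    r = y - X @ beta
    n_g = np.bincount(cidx, minlength=G).astype(float)
    S = sigma2 + n_g * phi
    T = _csum(cidx, G, r)
    rr = _csum(cidx, G, r * r)
    quad = rr / sigma2 - phi * T * T / (sigma2 * S)
    logdet = (n_g - 1.0) * np.log(sigma2) + np.log(S)
    return -0.5 * (n_g * _LOG2PI + logdet + quad)


def mlm_cluster_scores(
    y: np.ndarray,
    X: np.ndarray,
    cidx: np.ndarray,
    G: int,
    beta: np.ndarray,
    phi: float,
    sigma2: float,
) -> np.ndarray:
    """Per-cluster score vectors, shape (G, p + 2), order (beta..., phi, sigma2)."""
    r = y - X @ beta
    n_g = np.bincount(cidx, minlength=G).astype(float)
    S = sigma2 + n_g * phi
    T = _csum(cidx, G, r)
    # w = Sigma^{-1} r, row-wise
    w = r / sigma2 - (phi * T / (sigma2 * S))[cidx]
    p = X.shape[1]
    out = np.empty((G, p + 2))
    for k in range(p):
        out[:, k] = _csum(cidx, G, X[:, k] * w)
    out[:, p] = -0.5 * n_g / S + 0.5 * (T / S) ** 2
    ww = _csum(cidx, G, w * w)
    out[:, p + 1] = -0.5 * ((n_g - 1.0) / sigma2 + 1.0 / S) + 0.5 * ww
    return out


def mlm_hessian(
    y: np.ndarray,
    X: np.ndarray,
    cidx: np.ndarray,
    G: int,
    beta: np.ndarray,
    phi: float,
    sigma2: float,
) -> np.ndarray:
    """Observed Hessian of the total log-likelihood wrt (beta, phi, sigma2)."""
    r = y - X @ beta
    n_g = np.bincount(cidx, minlength=G).astype(float)
    S = sigma2 + n_g * phi
    T = _csum(cidx, G, r)
    p = X.shape[1]
    # per-cluster column sums of X
    A = np.empty((G, p))
    for k in range(p):
        A[:, k] = _csum(cidx, G, X[:, k])
    w = r / sigma2 - (phi * T / (sigma2 * S))[cidx]  # Sigma^{-1} r
    W = _csum(cidx, G, w)  # equals T / S
    v = w / sigma2 - (phi * W / (sigma2 * S))[cidx]  # Sigma^{-2} r

    H = np.zeros((p + 2, p + 2))
    # beta-beta: -X' Sigma^{-1} X = -(X'X)/sigma2 + sum_g c_g a_g a_g'
    c = phi / (sigma2 * S)
    H[:p, :p] = -(X.T @ X) / sigma2 + (A * c[:, None]).T @ A
    # beta-phi: -sum_g a_g T_g / S_g^2
    H[:p, p] = H[p, :p] = -(A * (T / S**2)[:, None]).sum(axis=0)
    # beta-sigma2: -X' Sigma^{-2} r
    H[:p, p + 1] = H[p + 1, :p] = -(X * v[:, None]).sum(axis=0)
    # phi-phi, phi-sigma2
    H[p, p] = np.sum(n_g**2 / (2.0 * S**2) - n_g * T**2 / S**3)
    H[p, p + 1] = H[p + 1, p] = np.sum(n_g / (2.0 * S**2) - T**2 / S**3)
    # sigma2-sigma2: 0.5 (n-1)/sigma2^2 + 0.5/S^2 - r' Sigma^{-3} r
    u = v / sigma2 - (phi * _csum(cidx, G, v) / (sigma2 * S))[cidx]  # Sigma^{-3} r
    H[p + 1, p + 1] = float(
        np.sum(0.5 * (n_g - 1.0) / sigma2**2 + 0.5 / S**2) - np.dot(r, u)
    )
    return H


def gls_beta(
    y: np.ndarray,
    X: np.ndarray,
    cidx: np.ndarray,
    G: int,
    phi: float,
    sigma2: float,
) -> np.ndarray:
    """Closed-form GLS fixed effects given the variance components."""
    n_g = np.bincount(cidx, minlength=G).astype(float)
    S = sigma2 + n_g * phi
    c = phi / (sigma2 * S)
    p = X.shape[1]
    A = np.empty((G, p))
    for k in range(p):
        A[:, k] = _csum(cidx, G, X[:, k])
    t = _csum(cidx, G, y)
    XtVX = (X.T @ X) / sigma2 - (A * c[:, None]).T @ A
    XtVy = (X.T @ y) / sigma2 - A.T @ (c * t)
    return np.linalg.solve(XtVX, XtVy)


# ---------------------------------------------------------------------------
# Censored (Tobit) likelihood via adaptive Gauss--Hermite quadrature
# ---------------------------------------------------------------------------


def _inv_mills(a: np.ndarray) -> np.ndarray:
    """phi(a) / Phi(a), stable in the deep lower tail."""
    return np.exp(-0.5 * a * a - 0.5 * _LOG2PI - log_ndtr(a))


def _posterior_mode(
    resid: np.ndarray,
    a_lo_base: Optional[np.ndarray],
    b_hi_base: Optional[np.ndarray],
    unc: np.ndarray,
    cl: np.ndarray,
    ch: np.ndarray,
    cidx: np.ndarray,
    G: int,
    phi: float,
    sigma: float,
    max_iter: int = 60,
    tol: float = 1e-11,
) -> Tuple[np.ndarray, np.ndarray]:
    """Mode and curvature of the per-cluster log-integrand in u.

    ``resid`` is y - X beta for uncensored rows; ``a_lo_base`` is
    (l - mu)/sigma for floored rows, ``b_hi_base`` (h - mu)/sigma for
    ceilinged rows.  Returns (u_hat, -h''(u_hat)); the log-integrand is
    strictly concave so Newton with step clipping converges globally.
    """
    sigma2 = sigma * sigma
    u = np.zeros(G)
    step_cap = 5.0 * np.sqrt(phi + sigma2)
    neg_h2 = np.full(G, 1.0 / phi)
    for _ in range(max_iter):
        g1 = -u / phi
        g2 = np.full(G, -1.0 / phi)
        if unc.any():
            ru = resid[unc] - u[cidx[unc]]
            g1 += _csum(cidx[unc], G, ru) / sigma2
            g2 -= np.bincount(cidx[unc], minlength=G) / sigma2
        if cl.any():
            a = a_lo_base[cl] - u[cidx[cl]] / sigma
            lam = _inv_mills(a)
            g1 += _csum(cidx[cl], G, -lam / sigma)
            g2 += _csum(cidx[cl], G, (-a * lam - lam * lam)) / sigma2
        if ch.any():
            b = b_hi_base[ch] - u[cidx[ch]] / sigma
            lam = _inv_mills(-b)
            g1 += _csum(cidx[ch], G, lam / sigma)
            g2 += _csum(cidx[ch], G, (b * lam - lam * lam)) / sigma2
        step = g1 / (-g2)
        np.clip(step, -step_cap, step_cap, out=step)
        u = u + step
        neg_h2 = -g2
        if np.max(np.abs(step)) < tol:
            break
    return u, neg_h2


def tobit_cluster_logliks(
    y: np.ndarray,
    X: np.ndarray,
    cidx: np.ndarray,
    G: int,
    cens_low: np.ndarray,
    cens_high: np.ndarray,
    lower: Optional[float],
    upper: Optional[float],
    beta: np.ndarray,
    phi: float,
    sigma2: float,
    n_nodes: int,
) -> np.ndarray:
    """Per-cluster censored-data log marginal likelihood contributions."""
    sigma = float(np.sqrt(sigma2))
    phi = max(float(phi), 1e-300)
    mu = X @ beta
    unc = ~(cens_low | cens_high)
    resid = np.where(unc, y - mu, 0.0)
    a_lo = (lower - mu) / sigma if lower is not None else None
    b_hi = (upper - mu) / sigma if upper is not None else None

    u_hat, curv = _posterior_mode(
        resid, a_lo, b_hi, unc, cens_low, cens_high, cidx, G, phi, sigma
    )
    tau = 1.0 / np.sqrt(curv)

    z, wts = hermgauss(n_nodes)
    # nodes per cluster: shape (G, K)
    U = u_hat[:, None] + np.sqrt(2.0) * tau[:, None] * z[None, :]

    logint = -0.5 * (U * U) / phi - 0.5 * (_LOG2PI + np.log(phi))
    if unc.any():
        ci = cidx[unc]
        ru = resid[unc][:, None] - U[ci, :]
        contrib = -0.5 * (ru / sigma) ** 2 - np.log(sigma) - 0.5 * _LOG2PI
        for k in range(n_nodes):
            logint[:, k] += _csum(ci, G, contrib[:, k])
    if cens_low.any():
        ci = cidx[cens_low]
        a = a_lo[cens_low][:, None] - U[ci, :] / sigma
        contrib = log_ndtr(a)
        for k in range(n_nodes):
            logint[:, k] += _csum(ci, G, contrib[:, k])
    if cens_high.any():
        ci = cidx[cens_high]
        b = b_hi[cens_high][:, None] - U[ci, :] / sigma
        contrib = log_ndtr(-b)
        for k in range(n_nodes):
            logint[:, k] += _csum(ci, G, contrib[:, k])

    # log ∫ f(u) du ≈ logsumexp_k [log w_k + z_k^2 + log f(U_gk)] + log(sqrt(2) tau_g)
    lw = np.log(wts) + z * z
    M = logint + lw[None, :]
    mmax = M.max(axis=1)
    out = mmax + np.log(np.exp(M - mmax[:, None]).sum(axis=1))
    out += 0.5 * np.log(2.0) + np.log(tau)
    return out
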