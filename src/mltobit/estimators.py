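"""Estimators for two-level data with a floored outcome.

Three ways of fitting the random-intercept regression are provided, matching
the three analysis strategies commonly compared for floor-affected scores:

``naive_ml``
    ordinary maximum likelihood that treats floored values as if observed
    (:class:`MultilevelRegression` with model-based standard errors);
``robust``
    the same point estimates with cluster-robust sandwich standard errors,
    an analogue of the MLR estimator (``se="cluster_robust"``);
``tobit``
    full maximum likelihood for the censored outcome
    (:class:`MultilevelTobit`), integrating the random intercept by adaptive
    Gauss--Hermite quadrature.

The classes follow the scikit-learn estimator contract (``fit(X, y,
groups=...)``, ``get_params``/``set_params``, trailing-underscore fitted
attributes); the module-level functions ``fit_naive_ml``/``robust_se``/
``fit_tobit``/``wald_infer`` are thin wrappers operating on
:class:`~mltobit.model_core.TwoLevelDataset`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.stats import norm
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from . import _likelihood as _lik
from .model_core import (
    CensoringError,
    CensoringSpec,
    EmptyDataError,
    FitResult,
    InvalidParameterError,
    TwoLevelDataset,
)

__all__ = [
    "MultilevelRegression",
    "MultilevelTobit",
    "InferenceResult",
    "fit_naive_ml",
    "robust_se",
    "fit_tobit",
    "wald_infer",
]

_LOG_VAR_FLOOR = -30.0  # variance parameters are optimised as log(var) >= -30
_PHI_BOUNDARY = 1e-10  # below this the between-variance is treated as at 0


class SingularDesignError(np.linalg.LinAlgError):
    """Fixed-effect design is rank deficient."""


class InsufficientClustersError(ValueError):
    """Fewer clusters than the method requires."""


class DegenerateDataError(ValueError):
    """No information left to fit (e.g., every row censored)."""


@dataclass(frozen=True)
class InferenceResult:
    """Wald z-test for a single fixed effect (two-tailed, alpha = 0.05)."""

    parameter: str
    estimate: float
    std_error: float
    z_statistic: float
    two_sided_p: float
    significant_at_005: bool


# ---------------------------------------------------------------------------
# shared helpers
# ---------------------------------------------------------------------------


def _validate_design(X: np.ndarray) -> None:
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise SingularDesignError(
            f"design matrix is rank deficient (rank < {X.shape[1]})"
        )


def _groups_to_codes(groups) -> Tuple[np.ndarray, int]:
    codes, uniques = pd.factorize(np.asarray(groups))
    return codes.astype(np.intp), len(uniques)


def _num_hessian(f: Callable[[np.ndarray], float], x: np.ndarray, rel_step: float = 1e-4) -> np.ndarray:
    """Central-difference Hessian of a scalar function."""
    p = len(x)
    h = rel_step * np.maximum(1.0, np.abs(x))
    H = np.empty((p, p))
    f0 = f(x)
    for i in range(p):
        ei = np.zeros(p)
        ei[i] = h[i]
        H[i, i] = (f(x + ei) - 2.0 * f0 + f(x - ei)) / h[i] ** 2
        for j in range(i + 1, p):
            ej = np.zeros(p)
            ej[j] = h[j]
            H[i, j] = H[j, i] = (
                f(x + ei + ej) - f(x + ei - ej) - f(x - ei + ej) + f(x - ei - ej)
            ) / (4.0 * h[i] * h[j])
    return H


def _invert_information(
    A: np.ndarray, phi_index: int, phi_at_boundary: bool
) -> np.ndarray:
    """Invert the observed information, dropping phi when it sits at zero.

    At the boundary (or with singleton clusters) phi and sigma2 are not
    separately identified and the full information matrix is singular; the
    phi row/column is then excluded and reported as NaN.
    """
    p = A.shape[0]
    if not phi_at_boundary:
        return np.linalg.inv(A)
    keep = [i for i in range(p) if i != phi_index]
    out = np.full((p, p), np.nan)
    sub = np.linalg.inv(A[np.ix_(keep, keep)])
    out[np.ix_(keep, keep)] = sub
    return out


def _sandwich_vcov(
    y: np.ndarray,
    X: np.ndarray,
    cidx: np.ndarray,
    G: int,
    beta: np.ndarray,
    phi: float,
    sigma2: float,
    small_sample_correction: bool,
) -> np.ndarray:
    """Cluster sandwich A^{-1} B A^{-1} on the natural parameter scale."""
    p = X.shape[1]
    A = -_lik.mlm_hessian(y, X, cidx, G, beta, phi, sigma2)
    scores = _lik.mlm_cluster_scores(y, X, cidx, G, beta, phi, sigma2)
    B = scores.T @ scores
    at_boundary = phi < _PHI_BOUNDARY
    if at_boundary:
        keep = [i for i in range(p + 2) if i != p]
        Ainv = np.linalg.inv(A[np.ix_(keep, keep)])
        Bsub = B[np.ix_(keep, keep)]
        V = np.full((p + 2, p + 2), np.nan)
        V[np.ix_(keep, keep)] = Ainv @ Bsub @ Ainv
    else:
        Ainv = np.linalg.inv(A)
        V = Ainv @ B @ Ainv
    if small_sample_correction:
        V = V * (G / (G - 1.0))
    return V


def _make_result(
    method: str,
    names: Sequence[str],
    beta: np.ndarray,
    phi: float,
    sigma2: float,
    vcov: np.ndarray,
    loglik: float,
    converged: bool,
    n_iter: int,
    n_obs: int,
    G: int,
    message: str = "",
) -> FitResult:
    all_names = list(names) + ["var_between", "var_within"]
    est = pd.Series(np.concatenate([beta, [phi, sigma2]]), index=all_names)
    with np.errstate(invalid="ignore"):
        se = pd.Series(np.sqrt(np.diag(vcov)), index=all_names)
    return FitResult(
        method=method,
        estimates=est,
        std_errors=se,
        vcov=pd.DataFrame(vcov, index=all_names, columns=all_names),
        loglik=loglik,
        converged=converged,
        n_iter=n_iter,
        n_obs=n_obs,
        n_clusters=G,
        fixed_effect_names=tuple(names),
        message=message,
    )


def _starting_variances(
    y: np.ndarray, X: np.ndarray, cidx: np.ndarray, G: int
) -> Tuple[np.ndarray, float, float]:
    """OLS fixed effects plus moment starting values for (phi, sigma2)."""
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    r = y - X @ beta
    n_g = np.bincount(cidx, minlength=G).astype(float)
    rbar = _lik._csum(cidx, G, r) / n_g
    within = r - rbar[cidx]
    dof = max(len(y) - G, 1)
    sigma2 = max(float(np.sum(within**2) / dof), 1e-6)
    phi = max(float(np.var(rbar) - sigma2 / n_g.mean()), 0.05 * sigma2)
    return beta, phi, sigma2


# ---------------------------------------------------------------------------
# estimator classes
# ---------------------------------------------------------------------------


class MultilevelRegression(RegressorMixin, BaseEstimator):
    """Random-intercept linear regression fitted by maximum likelihood.

    Censoring in the outcome is ignored: floored values are treated as
    ordinary observations.  Standard errors are model-based (inverse observed
    information) or cluster-robust (sandwich), selected by ``se``; both
    covariance matrices are computed and kept.

    Parameters
    ----------
    se : {"model", "cluster_robust"}
        Which standard errors the fitted ``result_`` reports.
    small_sample_correction : bool
        Apply the G/(G-1) factor to the sandwich (G = number of clusters).
    tol : float
        Optimiser tolerance on the profile log-likelihood.
    max_iter : int
        Maximum optimiser iterations.

    Attributes
    ----------
    intercept_ : float
    coef_ : ndarray of shape (n_covariates,)
    var_between_ : float
        Cluster random-intercept variance estimate.
    var_within_ : float
        Level-1 residual variance estimate.
    loglik_ : float
    vcov_model_, vcov_robust_ : DataFrame
        Covariance of all parameter estimates, model-based and sandwich.
    result_ : FitResult
    """

    def __init__(
        self,
        se: str = "model",
        small_sample_correction: bool = True,
        tol: float = 1e-9,
        max_iter: int = 200,
    ) -> None:
        self.se = se
        self.small_sample_correction = small_sample_correction
        self.tol = tol
        self.max_iter = max_iter

    def fit(self, X, y, groups=None, feature_names: Optional[Sequence[str]] = None):
        if groups is None:
            raise ValueError("groups (cluster labels, one per row) is required")
        if self.se not in ("model", "cluster_robust"):
            raise ValueError(f"se must be 'model' or 'cluster_robust', got {self.se!r}")
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        y = np.asarray(y, dtype=float)
        cidx, G = _groups_to_codes(groups)
        if G < 2:
            raise InsufficientClustersError("need at least 2 clusters")
        D = np.column_stack([np.ones(len(y)), X])
        _validate_design(D)
        if feature_names is None:
            feature_names = [f"x{i + 1}" for i in range(X.shape[1])]
        names = ["intercept"] + list(feature_names)

        singleton_only = np.bincount(cidx, minlength=G).max() == 1
        if singleton_only:
            # without within-cluster replication phi is not identified (only
            # phi + sigma2 is); pin phi at zero, where ML has a closed form
            beta, *_ = np.linalg.lstsq(D, y, rcond=None)
            phi = float(np.exp(_LOG_VAR_FLOOR))
            sigma2 = float(np.mean((y - D @ beta) ** 2))
            converged, n_iter, message = True, 0, "closed form (singleton clusters)"
        else:
            _, phi0, sig0 = _starting_variances(y, D, cidx, G)

            def profile_nll(theta: np.ndarray) -> float:
                phi, s2 = np.exp(theta)
                b = _lik.gls_beta(y, D, cidx, G, phi, s2)
                return -float(
                    _lik.mlm_cluster_logliks(y, D, cidx, G, b, phi, s2).sum()
                )

            res = optimize.minimize(
                profile_nll,
                x0=np.log([phi0, sig0]),
                method="L-BFGS-B",
                bounds=[(_LOG_VAR_FLOOR, 10.0)] * 2,
                options={"ftol": 1e-13, "gtol": 1e-8, "maxiter": self.max_iter},
            )
            phi, sigma2 = np.exp(res.x)
            beta = _lik.gls_beta(y, D, cidx, G, phi, sigma2)
            converged, n_iter, message = bool(res.success), int(res.nit), str(res.message)
        loglik = float(_lik.mlm_cluster_logliks(y, D, cidx, G, beta, phi, sigma2).sum())

        p = D.shape[1]
        A = -_lik.mlm_hessian(y, D, cidx, G, beta, phi, sigma2)
        at_boundary = phi < _PHI_BOUNDARY
        vcov_model = _invert_information(A, p, at_boundary)
        vcov_robust = _sandwich_vcov(
            y, D, cidx, G, beta, phi, sigma2, self.small_sample_correction
        )

        method = "naive_ml" if self.se == "model" else "robust"
        vcov = vcov_model if self.se == "model" else vcov_robust
        self.result_ = _make_result(
            method,
            names,
            beta,
            phi,
            sigma2,
            vcov,
            loglik,
            converged,
            n_iter,
            len(y),
            G,
            message=message,
        )
        all_names = names + ["var_between", "var_within"]
        self.vcov_model_ = pd.DataFrame(vcov_model, index=all_names, columns=all_names)
        self.vcov_robust_ = pd.DataFrame(
            vcov_robust, index=all_names, columns=all_names
        )
        self.intercept_ = float(beta[0])
        self.coef_ = beta[1:].copy()
        self.var_between_ = float(phi)
        self.var_within_ = float(sigma2)
        self.loglik_ = loglik
        self.converged_ = converged
        self.n_iter_ = n_iter
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X) -> np.ndarray:
        """Fixed-effect (population-level) prediction."""
        check_is_fitted(self, "coef_")
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        return self.intercept_ + X @ self.coef_


class MultilevelTobit(RegressorMixin, BaseEstimator):
    """Random-intercept regression for a left- and/or right-censored outcome.

    Rows at the floor contribute the normal lower-tail probability
    Phi((l - mu_ij - u_j)/sigma), rows at the ceiling the upper tail, and
    the cluster random intercept u_j is integrated out by adaptive
    Gauss--Hermite quadrature with ``n_nodes`` nodes recentred at each
    cluster's posterior mode.  Variance components are optimised on the log
    scale; their standard errors are returned on the natural scale by the
    delta method.

    Parameters
    ----------
    lower, upper : float, optional
        Censoring thresholds.  At least one must be given (otherwise the
        model reduces to :class:`MultilevelRegression`).
    n_nodes : int
        Quadrature nodes (default 21).
    tol, max_iter : optimiser controls.
    """

    def __init__(
        self,
        lower: Optional[float] = None,
        upper: Optional[float] = None,
        n_nodes: int = 21,
        tol: float = 1e-9,
        max_iter: int = 500,
    ) -> None:
        self.lower = lower
        self.upper = upper
        self.n_nodes = n_nodes
        self.tol = tol
        self.max_iter = max_iter

    def fit(
        self,
        X,
        y,
        groups=None,
        censored_low: Optional[np.ndarray] = None,
        censored_high: Optional[np.ndarray] = None,
        feature_names: Optional[Sequence[str]] = None,
    ):
        if groups is None:
            raise ValueError("groups (cluster labels, one per row) is required")
        if self.n_nodes < 1:
            raise InvalidParameterError("n_nodes must be >= 1")
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        y = np.asarray(y, dtype=float)
        cidx, G = _groups_to_codes(groups)
        if G < 2:
            raise InsufficientClustersError("need at least 2 clusters")
        D = np.column_stack([np.ones(len(y)), X])
        _validate_design(D)
        if feature_names is None:
            feature_names = [f"x{i + 1}" for i in range(X.shape[1])]
        names = ["intercept"] + list(feature_names)

        if censored_low is None:
            censored_low = (
                y <= self.lower if self.lower is not None else np.zeros(len(y), bool)
            )
        else:
            censored_low = np.asarray(censored_low, dtype=bool)
            if censored_low.any() and self.lower is None:
                raise CensoringError("censored_low flags given but lower is None")
        if censored_high is None:
            censored_high = (
                y >= self.upper if self.upper is not None else np.zeros(len(y), bool)
            )
        else:
            censored_high = np.asarray(censored_high, dtype=bool)
            if censored_high.any() and self.upper is None:
                raise CensoringError("censored_high flags given but upper is None")
        p_cens = float(np.mean(censored_low | censored_high))
        if p_cens >= 1.0:
            raise DegenerateDataError("every row is censored")

        # warm start at the naive fit, residual variance de-attenuated
        start = MultilevelRegression().fit(X, y, groups=groups)
        beta0 = np.concatenate([[start.intercept_], start.coef_])
        sig0 = start.var_within_ / max(1.0 - p_cens, 0.25)
        phi0 = max(start.var_between_, 1e-4)
        x0 = np.concatenate([beta0, np.log([phi0, sig0])])
        pfe = D.shape[1]

        def nll(theta: np.ndarray) -> float:
            beta = theta[:pfe]
            phi, s2 = np.exp(theta[pfe:])
            ll = _lik.tobit_cluster_logliks(
                y,
                D,
                cidx,
                G,
                censored_low,
                censored_high,
                self.lower,
                self.upper,
                beta,
                phi,
                s2,
                self.n_nodes,
            ).sum()
            if not np.isfinite(ll):
                return 1e12
            return -float(ll)

        bounds = [(None, None)] * pfe + [(_LOG_VAR_FLOOR, 10.0)] * 2
        if np.bincount(cidx, minlength=G).max() == 1:
            # phi unidentified without within-cluster replication; pin at zero
            bounds[pfe] = (_LOG_VAR_FLOOR, _LOG_VAR_FLOOR)
            x0[pfe] = _LOG_VAR_FLOOR
        res = optimize.minimize(
            nll,
            x0=x0,
            method="L-BFGS-B",
            bounds=bounds,
            options={"ftol": 1e-12, "gtol": 1e-7, "maxiter": self.max_iter},
        )
        beta = res.x[:pfe]
        phi, sigma2 = np.exp(res.x[pfe:])
        loglik = -float(res.fun)

        # observed information on the internal (beta, log phi, log sigma2) scale
        H = _num_hessian(nll, res.x)
        at_boundary = phi < _PHI_BOUNDARY
        vcov_theta = _invert_information(H, pfe, at_boundary)
        J = np.ones(pfe + 2)
        J[pfe], J[pfe + 1] = phi, sigma2  # d(var)/d(log var)
        vcov = vcov_theta * np.outer(J, J)

        self.result_ = _make_result(
            "tobit",
            names,
            beta,
            phi,
            sigma2,
            vcov,
            loglik,
            bool(res.success),
            int(res.nit),
            len(y),
            G,
            message=str(res.message),
        )
        self.intercept_ = float(beta[0])
        self.coef_ = beta[1:].copy()
        self.var_between_ = float(phi)
        self.var_within_ = float(sigma2)
        self.loglik_ = loglik
        self.converged_ = bool(res.success)
        self.n_iter_ = int(res.nit)
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X) -> np.ndarray:
        """Latent (uncensored) mean prediction."""
        check_is_fitted(self, "coef_")
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        return self.intercept_ + X @ self.coef_


# ---------------------------------------------------------------------------
# dataset-level functional surface
# ---------------------------------------------------------------------------


def _dataset_arrays(data: TwoLevelDataset):
    X = data.frame[list(data.covariates)].to_numpy(dtype=float)
    return X, data.y_obs, data.frame["cluster_id"].to_numpy(), list(data.covariates)


def fit_naive_ml(data: TwoLevelDataset) -> FitResult:
    """ML fit of the random-intercept model, floors treated as observed."""
    X, y, groups, names = _dataset_arrays(data)
    est = MultilevelRegression(se="model").fit(X, y, groups=groups, feature_names=names)
    return est.result_


def robust_se(fit: FitResult, data: TwoLevelDataset) -> FitResult:
    """Replace model-based SEs with the cluster sandwich at the same estimates.

    The point estimates pass through unchanged; only the covariance (and
    hence the standard errors) differ, with a G/(G-1) small-sample factor.
    """
    if fit.method != "naive_ml":
        raise ValueError("robust_se expects a naive_ml fit")
    if not fit.converged:
        raise ValueError("robust_se requires a converged fit")
    X, y, groups, names = _dataset_arrays(data)
    cidx, G = _groups_to_codes(groups)
    if G < 2:
        raise InsufficientClustersError("sandwich needs at least 2 clusters")
    D = np.column_stack([np.ones(len(y)), X])
    beta = fit.fixed_effects.to_numpy()
    phi = float(fit.estimates["var_between"])
    sigma2 = float(fit.estimates["var_within"])
    V = _sandwich_vcov(y, D, cidx, G, beta, phi, sigma2, True)
    return _make_result(
        "robust",
        fit.fixed_effect_names,
        beta,
        phi,
        sigma2,
        V,
        fit.loglik,
        fit.converged,
        fit.n_iter,
        fit.n_obs,
        G,
        message=fit.message,
    )


def fit_tobit(
    data: TwoLevelDataset,
    spec: Optional[CensoringSpec] = None,
    n_nodes: int = 21,
) -> FitResult:
    """ML fit of the censored random-intercept (multilevel Tobit) model."""
    if spec is None:
        spec = data.spec
    X, y, groups, names = _dataset_arrays(data)
    est = MultilevelTobit(lower=spec.lower, upper=spec.upper, n_nodes=n_nodes).fit(
        X,
        y,
        groups=groups,
        censored_low=data.censored_low,
        censored_high=data.censored_high,
        feature_names=names,
    )
    return est.result_


def wald_infer(fit: FitResult) -> List[InferenceResult]:
    """Two-tailed Wald z-tests for every fixed effect at alpha = 0.05."""
    if not fit.converged:
        raise ValueError("wald_infer requires a converged fit")
    out = []
    for name in fit.fixed_effect_names:
        est = float(fit.estimates[name])
        se = float(fit.std_errors[name])
        if not (se > 0):
            raise ZeroDivisionError(f"degenerate (non-positive) SE for {name!r}")
        z = est / se
        p = 2.0 * norm.sf(abs(z))
        out.append(
            InferenceResult(
                parameter=name,
                estimate=est,
                std_error=se,
                z_statistic=z,
                two_sided_p=p,
                significant_at_005=bool(p < 0.05),
            )
        )
    return out
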