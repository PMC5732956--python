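"""Domain types and log-likelihoods for the random-intercept model with a floored outcome.

The data model is a two-level (units nested in clusters) linear regression

    y*_ij = gamma00 + gamma10 * x1_ij + gamma01 * x2_j + u_j + e_ij,
    u_j ~ N(0, var_between),   e_ij ~ N(0, var_within),

where the latent outcome ``y*`` may only be observed within measurement
limits: values at or below a floor ``l`` are recorded as ``l`` (left-
censoring), values at or above a ceiling ``u`` as ``u`` (right-censoring).
Two likelihoods are provided:

* :func:`loglik_mlm` — the ordinary marginal likelihood of the
  random-intercept model, which ignores censoring (each cluster's outcome
  vector is multivariate normal with covariance ``var_within * I +
  var_between * J``);
* :func:`loglik_tobit` — the censored (Tobit) likelihood, in which censored
  rows contribute normal tail probabilities and the cluster random intercept
  is integrated out by adaptive Gauss--Hermite quadrature.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import _likelihood as _lik

__all__ = [
    "PopulationParams",
    "CensoringSpec",
    "TwoLevelDataset",
    "FitResult",
    "loglik_mlm",
    "loglik_tobit",
    "InvalidParameterError",
    "EmptyDataError",
    "CensoringError",
    "NumericalError",
]


class InvalidParameterError(ValueError):
    """Variance components or thresholds outside their admissible range."""


class EmptyDataError(ValueError):
    """A dataset with no rows (or no clusters) was supplied."""


class CensoringError(ValueError):
    """Censoring flags inconsistent with the declared thresholds."""


class NumericalError(FloatingPointError):
    """A likelihood evaluation produced a non-finite value."""


@dataclass(frozen=True)
class PopulationParams:
    """Fixed effects and variance components of the two-level model.

    Parameters
    ----------
    gamma00 : float
        Grand intercept (marginal mean of the latent outcome when the
        covariates are centred), in outcome units.
    gamma10 : float
        Level-1 (within-cluster) slope.
    gamma01 : float
        Level-2 (cluster covariate) slope.
    var_between : float
        Variance of the cluster random intercept, >= 0.
    var_within : float
        Level-1 residual variance, > 0.
    """

    gamma00: float = 1.0
    gamma10: float = 0.75
    gamma01: float = 0.5
    var_between: float = 0.5
    var_within: float = 1.0

    def __post_init__(self) -> None:
        if not (self.var_within > 0):
            raise InvalidParameterError(
                f"var_within must be > 0, got {self.var_within}"
            )
        if self.var_between < 0:
            raise InvalidParameterError(
                f"var_between must be >= 0, got {self.var_between}"
            )

    @property
    def beta(self) -> np.ndarray:
        """Fixed-effect vector ordered (intercept, x1 slope, x2 slope)."""
        return np.array([self.gamma00, self.gamma10, self.gamma01], dtype=float)

    def marginal_moments(
        self, var_x1: float = 1.0, var_x2: float = 1.0
    ) -> Tuple[float, float]:
        """Marginal mean and SD of the latent outcome.

        Assumes independent covariates with the given variances and zero
        means, so ``Var(Y) = gamma10**2 * var_x1 + gamma01**2 * var_x2 +
        var_between + var_within``.
        """
        var = (
            self.gamma10**2 * var_x1
            + self.gamma01**2 * var_x2
            + self.var_between
            + self.var_within
        )
        return self.gamma00, float(np.sqrt(var))


@dataclass(frozen=True)
class CensoringSpec:
    """Lower (floor) and/or upper (ceiling) censoring thresholds.

    An absent threshold means no censoring on that side.  Observed values at
    or beyond a threshold are recorded at the threshold; censoring at exact
    equality counts as censored.
    """

    lower: Optional[float] = None
    upper: Optional[float] = None

    def __post_init__(self) -> None:
        if self.lower is not None and self.upper is not None:
            if not (self.lower < self.upper):
                raise InvalidParameterError(
                    f"lower threshold ({self.lower}) must be < upper ({self.upper})"
                )

    @property
    def is_trivial(self) -> bool:
        return self.lower is None and self.upper is None


#: reserved column names in the tabular representation
RESERVED_COLUMNS = ("cluster_id", "y_obs", "censored_low", "censored_high", "y_latent")


@dataclass
class TwoLevelDataset:
    """Clustered observations with an (optionally censored) outcome.

    ``frame`` holds one row per level-1 unit with columns ``cluster_id``,
    ``y_obs``, ``censored_low``, ``censored_high``, an optional ``y_latent``
    (known only for synthetic data), and one column per covariate.
    ``covariates`` fixes the design order; ``cluster_covariates`` names the
    subset that is constant within clusters (level-2 covariates).
    """

    frame: pd.DataFrame
    spec: CensoringSpec = field(default_factory=CensoringSpec)
    covariates: Tuple[str, ...] = ("x1", "x2")
    cluster_covariates: Tuple[str, ...] = ("x2",)

    def __post_init__(self) -> None:
        if len(self.frame) == 0:
            raise EmptyDataError("dataset has no rows")
        missing = [
            c
            for c in ("cluster_id", "y_obs", "censored_low", "censored_high")
            if c not in self.frame.columns
        ]
        if missing:
            raise ValueError(f"dataset frame is missing columns {missing}")
        for c in self.covariates:
            if c not in self.frame.columns:
                raise ValueError(f"covariate column {c!r} not in frame")
        unknown = set(self.cluster_covariates) - set(self.covariates)
        if unknown:
            raise ValueError(f"cluster covariates {sorted(unknown)} not declared")

    # ---- array accessors -------------------------------------------------
    @property
    def n_obs(self) -> int:
        return len(self.frame)

    @property
    def n_clusters(self) -> int:
        return int(self.frame["cluster_id"].nunique())

    @property
    def y_obs(self) -> np.ndarray:
        return self.frame["y_obs"].to_numpy(dtype=float)

    @property
    def y_latent(self) -> Optional[np.ndarray]:
        if "y_latent" in self.frame.columns:
            return self.frame["y_latent"].to_numpy(dtype=float)
        return None

    @property
    def censored_low(self) -> np.ndarray:
        return self.frame["censored_low"].to_numpy(dtype=bool)

    @property
    def censored_high(self) -> np.ndarray:
        return self.frame["censored_high"].to_numpy(dtype=bool)

    def cluster_index(self) -> Tuple[np.ndarray, int]:
        """Dense 0..G-1 cluster codes (order of first appearance) and G."""
        codes, uniques = pd.factorize(self.frame["cluster_id"])
        return codes.astype(np.intp), len(uniques)

    def design_matrix(self) -> np.ndarray:
        """Fixed-effect design: a leading intercept column then covariates."""
        X = self.frame[list(self.covariates)].to_numpy(dtype=float)
        return np.column_stack([np.ones(len(X)), X])

    @property
    def fixed_effect_names(self) -> Tuple[str, ...]:
        return ("intercept",) + tuple(self.covariates)

    # ---- validation ------------------------------------------------------
    def validate(self) -> None:
        """Check the dataset invariants; raise on violation."""
        y = self.y_obs
        lo, hi = self.spec.lower, self.spec.upper
        if lo is not None and np.any(y < lo - 1e-12):
            raise CensoringError("y_obs below the lower threshold")
        if hi is not None and np.any(y > hi + 1e-12):
            raise CensoringError("y_obs above the upper threshold")
        if self.censored_low.any():
            if lo is None:
                raise CensoringError("censored_low flags set but no lower threshold")
            if not np.allclose(y[self.censored_low], lo):
                raise CensoringError("censored_low rows must sit at the threshold")
        if self.censored_high.any():
            if hi is None:
                raise CensoringError("censored_high flags set but no upper threshold")
            if not np.allclose(y[self.censored_high], hi):
                raise CensoringError("censored_high rows must sit at the threshold")
        yl = self.y_latent
        if yl is not None and lo is not None:
            if not np.array_equal(self.censored_low, yl <= lo):
                raise CensoringError("censored_low flags disagree with y_latent <= lower")
        for c in self.cluster_covariates:
            per = self.frame.groupby("cluster_id", sort=False)[c].nunique()
            if (per > 1).any():
                raise ValueError(f"cluster covariate {c!r} varies within a cluster")

    def with_spec(self, spec: CensoringSpec) -> "TwoLevelDataset":
        return replace(self, spec=spec)


@dataclass
class FitResult:
    """Point estimates, uncertainty and bookkeeping for one fitted model.

    ``estimates``/``std_errors`` are indexed by parameter name: the fixed
    effects (``intercept`` then the covariates in design order) followed by
    ``var_between`` and ``var_within``.  SEs of variance components are on
    the natural scale (delta method from the internally log-parameterised
    optimisation).  A variance at its positivity boundary gets a NaN SE.
    """

    method: str
    estimates: pd.Series
    std_errors: pd.Series
    vcov: pd.DataFrame
    loglik: float
    converged: bool
    n_iter: int
    n_obs: int
    n_clusters: int
    fixed_effect_names: Tuple[str, ...]
    message: str = ""

    def __post_init__(self) -> None:
        if self.method not in ("naive_ml", "robust", "tobit"):
            raise ValueError(f"unknown method {self.method!r}")

    @property
    def fixed_effects(self) -> pd.Series:
        return self.estimates[list(self.fixed_effect_names)]

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"estimate": self.estimates, "std_error": self.std_errors}
        )


# ---------------------------------------------------------------------------
# Spec-level likelihood evaluators
# ---------------------------------------------------------------------------


def _prepare(data: TwoLevelDataset):
    cidx, G = data.cluster_index()
    X = data.design_matrix()
    if G < 1:
        raise EmptyDataError("dataset has no clusters")
    return data.y_obs, X, cidx, G


def loglik_mlm(data: TwoLevelDataset, params: PopulationParams) -> float:
    """Marginal log-likelihood of the random-intercept model, censoring ignored.

    The random intercept is integrated out analytically: each cluster's
    outcome vector is multivariate normal around its fixed-effect mean with
    covariance ``var_within * I + var_between * J`` (J the all-ones matrix).

    Raises
    ------
    CensoringError
        If any row is flagged censored (this evaluator does not model
        censoring; use :func:`loglik_tobit`).
    """
    if data.censored_low.any() or data.censored_high.any():
        raise CensoringError("loglik_mlm cannot handle censored rows")
    y, X, cidx, G = _prepare(data)
    if X.shape[1] != len(params.beta):
        raise ValueError(
            "loglik_mlm expects the canonical (x1, x2) design; "
            f"got {X.shape[1] - 1} covariates"
        )
    ll = _lik.mlm_cluster_logliks(
        y, X, cidx, G, params.beta, params.var_between, params.var_within
    )
    total = float(ll.sum())
    if not np.isfinite(total):
        raise NumericalError(f"non-finite log-likelihood at {params}")
    return total


def loglik_tobit(
    data: TwoLevelDataset,
    params: PopulationParams,
    spec: Optional[CensoringSpec] = None,
    n_nodes: int = 21,
) -> float:
    """Censored-data log-likelihood, random intercept integrated numerically.

    For cluster j the contribution is

        log ∫ ∏_{uncensored i} φ((y_ij − μ_ij − u)/σ)/σ
              × ∏_{floored i} Φ((l − μ_ij − u)/σ)
              × ∏_{ceilinged i} Φ(−(h − μ_ij − u)/σ)
              × φ(u; 0, var_between) du ,

    evaluated by adaptive Gauss–Hermite quadrature with ``n_nodes`` nodes,
    recentred at each cluster's posterior mode of u with curvature-based
    scaling.  With no censored rows this agrees with :func:`loglik_mlm` to
    quadrature accuracy.
    """
    if spec is None:
        spec = data.spec
    if n_nodes < 1:
        raise InvalidParameterError("n_nodes must be >= 1")
    cl, ch = data.censored_low, data.censored_high
    if cl.any() and spec.lower is None:
        raise CensoringError("censored_low flags set but spec has no lower threshold")
    if ch.any() and spec.upper is None:
        raise CensoringError("censored_high flags set but spec has no upper threshold")
    y, X, cidx, G = _prepare(data)
    if X.shape[1] != len(params.beta):
        raise ValueError(
            "loglik_tobit expects the canonical (x1, x2) design; "
            f"got {X.shape[1] - 1} covariates"
        )
    ll = _lik.tobit_cluster_logliks(
        y,
        X,
        cidx,
        G,
        cl,
        ch,
        spec.lower,
        spec.upper,
        params.beta,
        params.var_between,
        params.var_within,
        n_nodes,
    )
    total = float(ll.sum())
    if not np.isfinite(total):
        raise NumericalError(
            f"non-finite censored log-likelihood at {params}, n_nodes={n_nodes}"
        )
    return total
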