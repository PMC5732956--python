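"""Monte Carlo harness comparing estimators across floor-effect severities.

The standard design crosses floor proportions {0, 5, 10, 15, 20, 25}% with
three analysis methods (naive ML, cluster-robust SEs, multilevel Tobit) and
summarises, per condition x method x parameter:

* relative bias of the point estimate, (mean estimate - truth)/truth;
* relative bias of the reported standard error, using the Monte-Carlo SD of
  that method's point estimates as the reference dispersion;
* 95% CI coverage and the Wald rejection rate;
* non-convergence counts (failed replications are excluded from summaries).

Replications are seeded from a single master seed through
``numpy.random.SeedSequence`` spawning, so results are reproducible and
independent of the degree of parallelism.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, List, Optional, Sequence

import numpy as np
import pandas as pd
from joblib import Parallel, delayed

from .estimators import fit_naive_ml, fit_tobit, robust_se
from .model_core import CensoringSpec, FitResult, PopulationParams
from .synthetic import (
    DesignConfig,
    FLOOR_THRESHOLDS,
    apply_floor,
    generate_two_level,
)

__all__ = [
    "SimulationCondition",
    "StudyResult",
    "default_conditions",
    "relative_bias",
    "se_relative_bias",
    "run_condition",
    "run_study",
    "summarize_study",
    "population_se",
]

METHODS = ("naive_ml", "robust", "tobit")
PARAMETERS = ("intercept", "x1", "x2", "var_between", "var_within")
Z95 = 1.959963984540054


@dataclass(frozen=True)
class SimulationCondition:
    """One floor-proportion condition of the Monte Carlo design."""

    label: int  # percent of outcomes at the floor (nominal)
    threshold: Optional[float]  # left-censoring point; None for the 0% baseline
    n_reps: int = 500
    design: DesignConfig = field(default_factory=DesignConfig)

    def __post_init__(self) -> None:
        if (self.threshold is None) != (self.label == 0):
            raise ValueError("threshold must be None exactly for the 0% condition")
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")


def default_conditions(
    n_reps: int = 500,
    design: Optional[DesignConfig] = None,
    labels: Sequence[int] = (0, 5, 10, 15, 20, 25),
) -> List[SimulationCondition]:
    """The standard six-condition design at the tabulated thresholds."""
    design = design or DesignConfig()
    return [
        SimulationCondition(
            label=lab, threshold=FLOOR_THRESHOLDS[lab], n_reps=n_reps, design=design
        )
        for lab in labels
    ]


def relative_bias(mean_estimate: float, truth: float) -> float:
    """(mean estimate - truth) / truth; undefined at truth = 0."""
    if truth == 0:
        raise ZeroDivisionError(
            "relative bias undefined for a zero true value; use absolute bias"
        )
    return (mean_estimate - truth) / truth


def se_relative_bias(mean_reported_se: float, mc_sd_of_estimates: float) -> float:
    """(mean reported SE - MC SD of estimates) / MC SD."""
    if not (mc_sd_of_estimates > 0):
        raise ZeroDivisionError("Monte-Carlo SD must be positive")
    return (mean_reported_se - mc_sd_of_estimates) / mc_sd_of_estimates


def _record(label: int, rep: int, method: str, fit: Optional[FitResult]) -> dict:
    row = {"label": label, "rep": rep, "method": method}
    if fit is None:
        row["converged"] = False
        for p in PARAMETERS:
            row[f"est_{p}"] = np.nan
            row[f"se_{p}"] = np.nan
        return row
    row["converged"] = bool(fit.converged)
    row["loglik"] = fit.loglik
    for p in PARAMETERS:
        row[f"est_{p}"] = float(fit.estimates[p])
        row[f"se_{p}"] = float(fit.std_errors[p])
    return row


def _one_replication(
    condition: SimulationCondition,
    methods: Sequence[str],
    rep: int,
    child_seed: np.random.SeedSequence,
    n_nodes: int,
) -> List[dict]:
    design = replace(condition.design, seed=child_seed)
    data = generate_two_level(design)
    if condition.threshold is not None:
        data = apply_floor(data, CensoringSpec(lower=condition.threshold))
    rows: List[dict] = []
    naive = None
    if "naive_ml" in methods or "robust" in methods:
        try:
            naive = fit_naive_ml(data)
        except Exception:
            naive = None
        if "naive_ml" in methods:
            rows.append(_record(condition.label, rep, "naive_ml", naive))
        if "robust" in methods:
            rob = None
            if naive is not None and naive.converged:
                try:
                    rob = robust_se(naive, data)
                except Exception:
                    rob = None
            rows.append(_record(condition.label, rep, "robust", rob))
    if "tobit" in methods:
        try:
            tob = fit_tobit(data, n_nodes=n_nodes)
        except Exception:
            tob = None
        rows.append(_record(condition.label, rep, "tobit", tob))
    return rows


def run_condition(
    condition: SimulationCondition,
    methods: Sequence[str] = METHODS,
    seed: int = 0,
    n_nodes: int = 21,
    n_jobs: int = 1,
) -> pd.DataFrame:
    """Generate-censor-fit for every replication of one condition.

    Returns one row per (replication, method) with point estimates, reported
    SEs and a convergence flag.  Deterministic for a given ``seed`` no matter
    the value of ``n_jobs``.
    """
    bad = set(methods) - set(METHODS)
    if bad:
        raise ValueError(f"unknown methods {sorted(bad)}")
    children = np.random.SeedSequence(seed).spawn(condition.n_reps)
    if n_jobs == 1:
        chunks = [
            _one_replication(condition, methods, r, children[r], n_nodes)
            for r in range(condition.n_reps)
        ]
    else:
        chunks = Parallel(n_jobs=n_jobs)(
            delayed(_one_replication)(condition, methods, r, children[r], n_nodes)
            for r in range(condition.n_reps)
        )
    rows = [row for chunk in chunks for row in chunk]
    out = pd.DataFrame(rows)
    frac_failed = 1.0 - out["converged"].mean()
    if frac_failed > 0.10:
        import warnings

        warnings.warn(
            f"condition {condition.label}%: {frac_failed:.0%} of fits failed to converge",
            RuntimeWarning,
            stacklevel=2,
        )
    return out


def run_study(
    conditions: Iterable[SimulationCondition],
    methods: Sequence[str] = METHODS,
    seed: int = 0,
    n_nodes: int = 21,
    n_jobs: int = 1,
) -> pd.DataFrame:
    """Run several conditions, each with its own spawned seed stream."""
    conditions = list(conditions)
    master = np.random.SeedSequence(seed)
    cond_seeds = master.generate_state(len(conditions)) % (2**31 - 1)
    frames = [
        run_condition(c, methods=methods, seed=int(s), n_nodes=n_nodes, n_jobs=n_jobs)
        for c, s in zip(conditions, cond_seeds)
    ]
    return pd.concat(frames, ignore_index=True)


def population_se(
    params: PopulationParams,
    design: Optional[DesignConfig] = None,
    threshold: Optional[float] = None,
    n_clusters_ref: int = 10000,
    n_nodes: int = 21,
    seed: int = 2**20,
) -> pd.Series:
    """Population standard errors of the correctly specified estimator.

    The "population value" of a standard error — the sampling dispersion a
    correct analysis of the design exhibits at the true parameters — is
    computed from the expected information of the correctly specified model
    (censored likelihood when a floor is present, plain multilevel
    likelihood otherwise).  The expectation is approximated by the observed
    information on one large simulated design of ``n_clusters_ref`` clusters
    evaluated at the true parameters, then rescaled to the target design's
    cluster count.  Relative SE bias measured against this reference (rather
    than against each estimator's own Monte-Carlo SD) isolates how much the
    floor shrinks a method's reported uncertainty relative to what the data
    actually support.
    """
    from .estimators import _num_hessian
    from . import _likelihood as _lik

    design = design or DesignConfig()
    big = replace(design, n_clusters=n_clusters_ref, params=params, seed=seed)
    data = generate_two_level(big)
    if threshold is not None:
        data = apply_floor(data, CensoringSpec(lower=threshold))
    y = data.y_obs
    X = data.design_matrix()
    cidx, G = data.cluster_index()
    beta = params.beta
    if threshold is None:
        A = -_lik.mlm_hessian(
            y, X, cidx, G, beta, params.var_between, params.var_within
        )
        V = np.linalg.inv(A)
    else:
        cl, ch = data.censored_low, data.censored_high

        def nll(theta: np.ndarray) -> float:
            b = theta[:3]
            phi, s2 = np.exp(theta[3:])
            return -float(
                _lik.tobit_cluster_logliks(
                    y, X, cidx, G, cl, ch, threshold, None, b, phi, s2, n_nodes
                ).sum()
            )

        theta0 = np.concatenate(
            [beta, np.log([params.var_between, params.var_within])]
        )
        H = _num_hessian(nll, theta0)
        V = np.linalg.inv(H)
        J = np.ones(5)
        J[3], J[4] = params.var_between, params.var_within
        V = V * np.outer(J, J)
    se = np.sqrt(np.diag(V) * (n_clusters_ref / design.n_clusters))
    return pd.Series(se, index=PARAMETERS)


_TRUTH_MAP = {
    "intercept": "gamma00",
    "x1": "gamma10",
    "x2": "gamma01",
    "var_between": "var_between",
    "var_within": "var_within",
}


@dataclass
class StudyResult:
    """Aggregated Monte Carlo summaries.

    ``summaries`` is indexed by (label, method, parameter) with full-precision
    columns; the ``*_table`` helpers pivot and round to 2 decimals for
    display.
    """

    summaries: pd.DataFrame
    nonconvergence: pd.DataFrame
    truth: PopulationParams

    def bias_table(self, parameter: str = "x1") -> pd.DataFrame:
        sub = self.summaries.xs(parameter, level="parameter")
        return sub["rel_bias"].unstack("method").round(2)

    def se_bias_table(self, parameter: str = "x1") -> pd.DataFrame:
        sub = self.summaries.xs(parameter, level="parameter")
        return sub["se_rel_bias"].unstack("method").round(2)

    def coverage_table(self, parameter: str = "x1") -> pd.DataFrame:
        sub = self.summaries.xs(parameter, level="parameter")
        return sub["coverage"].unstack("method").round(3)


def summarize_study(
    results: pd.DataFrame, truth: Optional[PopulationParams] = None
) -> StudyResult:
    """Collapse per-replication results into bias/coverage/power summaries.

    Non-converged replications are excluded (and counted).  Relative bias is
    reported where the true value is nonzero; coverage uses nominal 95%
    normal-theory intervals; the rejection rate is the two-tailed Wald test
    at the 5% level (power off the null, type I error under it).
    """
    truth = truth or PopulationParams()
    if len(results) == 0:
        raise ValueError("empty results")
    rows = []
    ncv = []
    for (label, method), grp in results.groupby(["label", "method"], sort=True):
        ok = grp[grp["converged"]]
        ncv.append(
            {
                "label": label,
                "method": method,
                "n_reps": len(grp),
                "n_failed": int(len(grp) - len(ok)),
            }
        )
        if len(ok) < 2:
            raise ValueError(
                f"cell (label={label}, method={method}) has <2 converged replications"
            )
        for p in PARAMETERS:
            est = ok[f"est_{p}"].to_numpy()
            se = ok[f"se_{p}"].to_numpy()
            tv = float(getattr(truth, _TRUTH_MAP[p]))
            mean_est = float(np.mean(est))
            mc_sd = float(np.std(est, ddof=1))
            have_se = np.isfinite(se)
            mean_se = float(np.mean(se[have_se])) if have_se.any() else np.nan
            rb = relative_bias(mean_est, tv) if tv != 0 else np.nan
            serb = (
                se_relative_bias(mean_se, mc_sd)
                if np.isfinite(mean_se) and mc_sd > 0
                else np.nan
            )
            with np.errstate(invalid="ignore"):
                covered = np.abs(est - tv) <= Z95 * se
                rejected = np.abs(est / se) > Z95
            rows.append(
                {
                    "label": label,
                    "method": method,
                    "parameter": p,
                    "truth": tv,
                    "mean_estimate": mean_est,
                    "mc_sd": mc_sd,
                    "mean_se": mean_se,
                    "rel_bias": rb,
                    "abs_bias": mean_est - tv,
                    "se_rel_bias": serb,
                    "coverage": float(np.mean(covered[have_se])) if have_se.any() else np.nan,
                    "rejection_rate": float(np.mean(rejected[have_se])) if have_se.any() else np.nan,
                    "n_converged": int(len(ok)),
                }
            )
    summaries = pd.DataFrame(rows).set_index(["label", "method", "parameter"])
    return StudyResult(
        summaries=summaries,
        nonconvergence=pd.DataFrame(ncv).set_index(["label", "method"]),
        truth=truth,
    )
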