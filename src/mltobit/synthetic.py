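"""Synthetic two-level data with controllable floor effects.

The canonical generator draws from the random-intercept model

    y*_ij = gamma00 + gamma10 * x1_ij + gamma01 * x2_j + u_j + e_ij

with x1 ~ N(0,1) per row, x2 ~ N(0,1) per cluster, u ~ N(0, var_between),
e ~ N(0, var_within).  With the default parameters (gamma = (1, 0.75, 0.5),
var_between = 0.5, var_within = 1) the latent outcome is marginally normal
with mean 1 and variance 2.3125; left-censoring at the standard thresholds
(-1.50, -0.95, -0.60, -0.25, 0.03) floors roughly 5/10/15/20/26% of rows.

A second generator produces "study-shaped" data emulating a classroom
intervention trial: named child-level covariates (pretest, demographics,
language-proficiency scores), classroom-level covariates including a
randomised binary intervention indicator, and a floored outcome.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple, Union

import numpy as np
import pandas as pd
from scipy.stats import norm

from .model_core import (
    CensoringSpec,
    EmptyDataError,
    InvalidParameterError,
    PopulationParams,
    TwoLevelDataset,
)

__all__ = [
    "DesignConfig",
    "StudyDesignConfig",
    "FLOOR_THRESHOLDS",
    "generate_two_level",
    "apply_floor",
    "threshold_for_proportion",
    "generate_study_like",
    "write_dataset",
    "read_dataset",
]

#: left-censoring points used for the standard floor-proportion conditions
#: (percent floored -> threshold in outcome units, under the default DGP)
FLOOR_THRESHOLDS: Dict[int, Optional[float]] = {
    0: None,
    5: -1.50,
    10: -0.95,
    15: -0.60,
    20: -0.25,
    25: 0.03,
}


@dataclass(frozen=True)
class DesignConfig:
    """Size, parameters and seed of one generated two-level dataset.

    Defaults give the standard design: 100 clusters of 10 units each
    (total n = 1,000).
    """

    n_clusters: int = 100
    cluster_size: int = 10
    params: PopulationParams = field(default_factory=PopulationParams)
    seed: Union[int, np.random.SeedSequence] = 0

    def __post_init__(self) -> None:
        if self.n_clusters < 2:
            raise InvalidParameterError("n_clusters must be >= 2")
        if self.cluster_size < 1:
            raise InvalidParameterError("cluster_size must be >= 1")

    @property
    def n_total(self) -> int:
        return self.n_clusters * self.cluster_size


def generate_two_level(config: DesignConfig) -> TwoLevelDataset:
    """Draw an uncensored dataset from the random-intercept model.

    ``y_latent`` is populated and ``y_obs`` equals it (no floor applied yet);
    the same seed always yields a bitwise-identical dataset.
    """
    p = config.params
    rng = np.random.default_rng(config.seed)
    G, m = config.n_clusters, config.cluster_size
    n = G * m
    cluster_id = np.repeat(np.arange(G), m)
    x2_cluster = rng.standard_normal(G)
    u0 = rng.standard_normal(G) * np.sqrt(p.var_between)
    x1 = rng.standard_normal(n)
    e = rng.standard_normal(n) * np.sqrt(p.var_within)
    y_latent = (
        p.gamma00
        + p.gamma01 * x2_cluster[cluster_id]
        + u0[cluster_id]
        + p.gamma10 * x1
        + e
    )
    frame = pd.DataFrame(
        {
            "cluster_id": cluster_id,
            "y_obs": y_latent,
            "censored_low": False,
            "censored_high": False,
            "x1": x1,
            "x2": x2_cluster[cluster_id],
            "y_latent": y_latent,
        }
    )
    return TwoLevelDataset(frame=frame, spec=CensoringSpec())


def apply_floor(data: TwoLevelDataset, spec: CensoringSpec) -> TwoLevelDataset:
    """Censor the latent outcome at the thresholds in ``spec``.

    Values with ``y_latent <= lower`` are recorded at the floor (censoring
    at exact equality counts as censored); an upper threshold is handled
    symmetrically.  Returns a new dataset; the input is not modified.
    """
    y_latent = data.y_latent
    if y_latent is None:
        raise ValueError("apply_floor requires y_latent")
    frame = data.frame.copy()
    y = y_latent.copy()
    cl = np.zeros(len(y), dtype=bool)
    ch = np.zeros(len(y), dtype=bool)
    if spec.lower is not None:
        cl = y_latent <= spec.lower
        y[cl] = spec.lower
    if spec.upper is not None:
        ch = y_latent >= spec.upper
        y[ch] = spec.upper
    frame["y_obs"] = y
    frame["censored_low"] = cl
    frame["censored_high"] = ch
    return TwoLevelDataset(
        frame=frame,
        spec=spec,
        covariates=data.covariates,
        cluster_covariates=data.cluster_covariates,
    )


def threshold_for_proportion(params: PopulationParams, p: float) -> float:
    """Floor threshold giving censoring probability ``p`` analytically.

    Under the generator the latent outcome is marginally normal with mean
    gamma00 and variance gamma10^2 + gamma01^2 + var_between + var_within
    (unit-variance covariates), so ``l = mu + sd * Phi^{-1}(p)``.
    """
    if not (0.0 < p < 1.0):
        raise InvalidParameterError(f"proportion must be in (0, 1), got {p}")
    mu, sd = params.marginal_moments()
    return float(mu + sd * norm.ppf(p))


# ---------------------------------------------------------------------------
# study-shaped data
# ---------------------------------------------------------------------------

#: (name, level, kind, default effect, default distribution parameter)
#: kind "normal" -> N(0,1); "binary" -> Bernoulli(param), centred at its mean
_STUDY_COVARIATES = (
    # child level
    ("pretest", 1, "normal", 0.50, None),
    ("age", 1, "normal", 0.05, None),
    ("gender", 1, "binary", 0.00, 0.5),
    ("bilingual", 1, "binary", -0.05, 0.85),
    ("ethnicity", 1, "binary", 0.00, 0.95),
    ("attendance", 1, "normal", 0.05, None),
    ("prelas_english", 1, "normal", 0.10, None),
    ("prelas_spanish", 1, "normal", 0.00, None),
    # classroom level
    ("district", 2, "binary", -0.20, 0.5),
    ("intervention", 2, "binary", 0.30, 0.5),
    ("teacher_language", 2, "binary", -0.10, 0.5),
    ("years_teaching", 2, "normal", -0.10, None),
    ("years_prek", 2, "normal", -0.05, None),
    ("reading_credits", 2, "normal", 0.20, None),
    ("prof_development", 2, "normal", 0.10, None),
)


@dataclass(frozen=True)
class StudyDesignConfig:
    """Configuration of the classroom-trial-shaped generator.

    Defaults emulate a two-district preschool trial: 42 classrooms of 6
    children (252 children), child-level pretest/demographic covariates and
    classroom-level teacher covariates with small-to-moderate effects in
    z-score units, a randomised binary intervention, and a floor censoring
    a chosen fraction of outcomes.  ``effects`` overrides individual
    coefficients by name.
    """

    n_clusters: int = 42
    cluster_size: int = 6
    intercept: float = 0.0
    effects: Dict[str, float] = field(default_factory=dict)
    var_between: float = 0.2
    var_within: float = 0.8
    floor_proportion: Optional[float] = 0.15

    def __post_init__(self) -> None:
        if self.n_clusters < 2 or self.cluster_size < 1:
            raise InvalidParameterError("need >= 2 clusters of >= 1 unit")
        known = {name for name, *_ in _STUDY_COVARIATES}
        unknown = set(self.effects) - known
        if unknown:
            raise InvalidParameterError(f"unknown covariate effects {sorted(unknown)}")
        if self.floor_proportion is not None and not (0 < self.floor_proportion < 1):
            raise InvalidParameterError("floor_proportion must be in (0, 1) or None")

    def effect_vector(self) -> Dict[str, float]:
        return {
            name: self.effects.get(name, default)
            for name, _, _, default, _ in _STUDY_COVARIATES
        }

    def marginal_moments(self) -> Tuple[float, float]:
        """Approximate marginal mean/SD of the latent outcome.

        Covariates are independent with unit variance (continuous) or
        p(1-p) (centred binary), so the variance adds across terms.
        """
        eff = self.effect_vector()
        var = self.var_between + self.var_within
        for name, _, kind, _, pr in _STUDY_COVARIATES:
            v = 1.0 if kind == "normal" else pr * (1.0 - pr)
            var += eff[name] ** 2 * v
        return self.intercept, float(np.sqrt(var))


def generate_study_like(
    config: StudyDesignConfig, seed: Union[int, np.random.SeedSequence] = 0
) -> TwoLevelDataset:
    """Generate a floored classroom-trial dataset with named covariates.

    Binary covariates are centred at their expected value so the intercept
    stays the marginal latent mean; the intervention indicator is kept 0/1
    (assigned to exactly half the classrooms, shuffled) so its coefficient
    reads as the treatment effect.  The floor threshold is placed at the
    analytic ``floor_proportion`` quantile of the latent outcome.
    """
    rng = np.random.default_rng(seed)
    G, m = config.n_clusters, config.cluster_size
    n = G * m
    cluster_id = np.repeat(np.arange(G), m)
    eff = config.effect_vector()

    cols: Dict[str, np.ndarray] = {}
    linpred = np.full(n, config.intercept)
    # balanced randomised intervention assignment at the classroom level
    interv = np.zeros(G)
    interv[: G // 2] = 1.0
    rng.shuffle(interv)
    for name, level, kind, _, pr in _STUDY_COVARIATES:
        size = G if level == 2 else n
        if name == "intervention":
            vals = interv
            centred = vals - 0.5
        elif kind == "normal":
            vals = rng.standard_normal(size)
            centred = vals
        else:
            vals = (rng.random(size) < pr).astype(float)
            centred = vals - pr
        if level == 2:
            vals = vals[cluster_id]
            centred = centred[cluster_id]
        cols[name] = vals
        linpred = linpred + eff[name] * centred

    u0 = rng.standard_normal(G) * np.sqrt(config.var_between)
    e = rng.standard_normal(n) * np.sqrt(config.var_within)
    y_latent = linpred + u0[cluster_id] + e

    frame = pd.DataFrame({"cluster_id": cluster_id})
    frame["y_obs"] = y_latent
    frame["censored_low"] = False
    frame["censored_high"] = False
    for name, *_ in _STUDY_COVARIATES:
        frame[name] = cols[name]
    frame["y_latent"] = y_latent

    l1 = tuple(n for n, lvl, *_ in _STUDY_COVARIATES if lvl == 1)
    l2 = tuple(n for n, lvl, *_ in _STUDY_COVARIATES if lvl == 2)
    data = TwoLevelDataset(
        frame=frame,
        spec=CensoringSpec(),
        covariates=l1 + l2,
        cluster_covariates=l2,
    )
    if config.floor_proportion is None:
        return data
    mu, sd = config.marginal_moments()
    lower = float(mu + sd * norm.ppf(config.floor_proportion))
    return apply_floor(data, CensoringSpec(lower=lower))


# ---------------------------------------------------------------------------
# delimited-text I/O
# ---------------------------------------------------------------------------


def write_dataset(data: TwoLevelDataset, path) -> None:
    """Write a dataset as CSV: cluster_id, y_obs, flags, covariates[, y_latent]."""
    lead = ["cluster_id", "y_obs", "censored_low", "censored_high"]
    cols = lead + list(data.covariates)
    if "y_latent" in data.frame.columns:
        cols.append("y_latent")
    data.frame[cols].to_csv(path, index=False)


def read_dataset(
    path,
    spec: Optional[CensoringSpec] = None,
    cluster_covariates: Optional[Tuple[str, ...]] = None,
) -> TwoLevelDataset:
    """Read a dataset written by :func:`write_dataset` (y_latent optional).

    Covariates are every non-reserved column, in file order.  If ``spec`` is
    omitted, a lower/upper threshold is inferred from the censored rows'
    common observed value (if any are flagged).
    """
    frame = pd.read_csv(path)
    if len(frame) == 0:
        raise EmptyDataError(f"no rows in {path}")
    reserved = {"cluster_id", "y_obs", "censored_low", "censored_high", "y_latent"}
    covariates = tuple(c for c in frame.columns if c not in reserved)
    frame["censored_low"] = frame["censored_low"].astype(bool)
    frame["censored_high"] = frame["censored_high"].astype(bool)
    if spec is None:
        lower = upper = None
        if frame["censored_low"].any():
            lower = float(frame.loc[frame["censored_low"], "y_obs"].iloc[0])
        if frame["censored_high"].any():
            upper = float(frame.loc[frame["censored_high"], "y_obs"].iloc[0])
        spec = CensoringSpec(lower=lower, upper=upper)
    if cluster_covariates is None:
        nunique = frame.groupby("cluster_id", sort=False)[list(covariates)].nunique()
        cluster_covariates = tuple(
            c for c in covariates if (nunique[c] <= 1).all()
        )
    return TwoLevelDataset(
        frame=frame,
        spec=spec,
        covariates=covariates,
        cluster_covariates=cluster_covariates,
    )
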