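"""Floor-effect screening for score vectors.

A practical screen for a floor effect in a test score distribution is the
15% rule: if 15% or more of a sample scores at the lowest attainable level
of the measure, a floor effect is likely and naive analyses of the scores
are suspect.  "Lowest level" is ambiguous between the observed minimum and
the instrument's nominal floor; the default uses the observed minimum and an
explicit ``scale_floor`` can be supplied, with both proportions reported.

For standard scores (normed mean 100, SD 15) the conventional descriptor
bands are also tabulated: <=69, 70-84, 85-99, 100-114, 115-129, 130+.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional

import numpy as np
import pandas as pd
from scipy import stats

from .model_core import EmptyDataError

__all__ = ["FloorDiagnostics", "detect_floor", "band_scores", "describe_distribution"]

#: descriptor bands for standard scores (closed integer bands)
STANDARD_SCORE_BANDS = (
    ("extremely_low", -np.inf, 69),
    ("moderately_low", 70, 84),
    ("low_average", 85, 99),
    ("high_average", 100, 114),
    ("moderately_high", 115, 129),
    ("extremely_high", 130, np.inf),
)


@dataclass(frozen=True)
class FloorDiagnostics:
    """Outcome of the floor-effect screen on one score vector."""

    n: int
    minimum: float
    proportion_at_minimum: float
    proportion_at_scale_floor: Optional[float]
    skewness: float
    floor_flag: bool
    rule_threshold: float
    band_counts: Optional[pd.DataFrame] = None


def detect_floor(
    scores,
    rule_threshold: float = 0.15,
    scale_floor: Optional[float] = None,
    bands: bool = False,
) -> FloorDiagnostics:
    """Apply the proportion-at-floor rule to a score vector.

    The flag is raised when the fraction of scores at the observed minimum
    (or at/below ``scale_floor`` when given) reaches ``rule_threshold``.
    Skewness is the adjusted Fisher-Pearson standardised third moment (NaN
    for n < 3 or constant input).
    """
    x = np.asarray(scores, dtype=float)
    if x.ndim != 1:
        x = x.ravel()
    if x.size == 0:
        raise EmptyDataError("no scores supplied")
    if np.isnan(x).any():
        raise ValueError("scores contain NaN")
    n = x.size
    mn = float(x.min())
    p_min = float(np.mean(x == mn))
    p_floor = None
    if scale_floor is not None:
        p_floor = float(np.mean(x <= scale_floor))
    rule_prop = p_floor if p_floor is not None else p_min
    skew = float(stats.skew(x, bias=False)) if n >= 3 and x.std() > 0 else float("nan")
    counts = band_scores(x) if bands else None
    return FloorDiagnostics(
        n=n,
        minimum=mn,
        proportion_at_minimum=p_min,
        proportion_at_scale_floor=p_floor,
        skewness=skew,
        floor_flag=bool(rule_prop >= rule_threshold),
        rule_threshold=rule_threshold,
        band_counts=counts,
    )


def band_scores(standard_scores) -> pd.DataFrame:
    """Count standard scores per descriptor band.

    Returns a frame indexed by band name with the score range, count and
    the percentage rounded to the nearest integer.  Bands are closed
    integer ranges (84 falls in 70-84, 85 in 85-99); non-integer scores
    land in the band whose range contains their floor.
    """
    x = np.asarray(standard_scores, dtype=float)
    if x.size == 0:
        raise EmptyDataError("no scores supplied")
    rows = []
    for name, lo, hi in STANDARD_SCORE_BANDS:
        in_band = (np.floor(x) >= lo) & (np.floor(x) <= hi)
        n = int(in_band.sum())
        if np.isinf(lo):
            rng = f"<={hi:g}"
        elif np.isinf(hi):
            rng = f"{lo:g}+"
        else:
            rng = f"{lo:g}-{hi:g}"
        rows.append({"band": name, "range": rng, "n": n})
    out = pd.DataFrame(rows).set_index("band")
    out["percentage"] = np.rint(100.0 * out["n"] / x.size).astype(int)
    return out


def describe_distribution(scores, bin_width: float = 5.0) -> Dict:
    """Deterministic distribution summary with fixed-width histogram bins.

    Bins are ``bin_width`` wide and aligned to multiples of ``bin_width``
    (so standard scores bin as 20-25, 25-30, ...).  Requires n >= 2 for the
    SD.
    """
    x = np.asarray(scores, dtype=float)
    if x.size < 2:
        raise EmptyDataError("need at least 2 scores for a distribution summary")
    lo = np.floor(x.min() / bin_width) * bin_width
    hi = np.ceil(x.max() / bin_width) * bin_width
    if hi <= lo:
        hi = lo + bin_width
    edges = np.arange(lo, hi + bin_width / 2, bin_width)
    counts, edges = np.histogram(x, bins=edges)
    return {
        "n": int(x.size),
        "mean": float(x.mean()),
        "sd": float(x.std(ddof=1)),
        "min": float(x.min()),
        "max": float(x.max()),
        "proportion_at_min": float(np.mean(x == x.min())),
        "skewness": float(stats.skew(x, bias=False)) if x.std() > 0 else float("nan"),
        "bin_edges": edges.tolist(),
        "bin_counts": counts.tolist(),
    }
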