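"""Distance- and size-effect regressors and their per-pair fits.

Three simple regressors over unordered numerosity pairs are supported, all
using the natural logarithm:

* ``value_distance``      ln(large - small) on the raw numerosities -- the
  value-based distance predictor.
* ``association_distance`` ln(rank_large - rank_small) on the 1-based ranks
  of the values within the session's ordered set -- the association-based
  predictor, which differs from the value-based one exactly when the value
  set is not equally spaced (e.g. an omitted middle range).
* ``size_sum``            (x1 + x2) / 5 -- the sum of the two "initial"
  numbers, i.e. the presented numerosities divided by five.

A useful identity: multiplying every value by a constant c shifts the
value-distance predictor by ln(c), so slopes and R^2 of a simple regression
are invariant under rescaling the value set while the intercept moves by
slope * ln(c). ``scale_invariance_check`` asserts this numerically.

On a complete all-pairs design over an arithmetic value grid, the
ln-difference distance regressor and the sum size regressor are orthogonal,
so simple and multiple regressions agree.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .design import ValueSet, order_map

__all__ = [
    "REGRESSOR_KINDS",
    "Regressor",
    "FitResult",
    "make_regressor",
    "fit_effect",
    "scale_invariance_check",
]

REGRESSOR_KINDS: Tuple[str, ...] = ("value_distance", "association_distance", "size_sum")

OUTCOME_COLUMNS = {"error_rate": "error_rate", "median_rt": "median_rt_ms"}


@dataclass(frozen=True)
class Regressor:
    """Per-unordered-pair predictor values."""

    kind: str
    basis: Dict[Tuple[int, int], float]

    def __getitem__(self, pair: Tuple[int, int]) -> float:
        small, large = min(pair), max(pair)
        return self.basis[(small, large)]


@dataclass(frozen=True)
class FitResult:
    """Simple-regression summary for one participant (or the group mean)."""

    participant_id: str
    kind: str
    outcome: str
    slope: float
    intercept: float
    r_squared: float


def make_regressor(kind: str, value_set: ValueSet | Sequence[int]) -> Regressor:
    if kind not in REGRESSOR_KINDS:
        raise ValueError(f"unknown regressor kind {kind!r}; expected {REGRESSOR_KINDS}")
    if not isinstance(value_set, ValueSet):
        value_set = ValueSet(value_set)
    if len(value_set) < 2:
        raise ValueError("need at least 2 values")
    vals = value_set.values
    ranks = order_map(value_set)
    basis: Dict[Tuple[int, int], float] = {}
    for i, small in enumerate(vals):
        for large in vals[i + 1 :]:
            if kind == "value_distance":
                basis[(small, large)] = float(np.log(large - small))
            elif kind == "association_distance":
                basis[(small, large)] = float(np.log(ranks[large] - ranks[small]))
            else:
                basis[(small, large)] = (small + large) / 5.0
    return Regressor(kind=kind, basis=basis)


def _simple_fit(x: np.ndarray, y: np.ndarray) -> Tuple[float, float, float]:
    """OLS slope/intercept/R^2; a constant outcome fits as a flat line."""
    if np.ptp(x) == 0:
        raise ValueError("zero variance in the predictor")
    if np.ptp(y) == 0:
        return 0.0, float(y[0]), 0.0
    res = stats.linregress(x, y)
    return float(res.slope), float(res.intercept), float(res.rvalue**2)


def fit_effect(
    stats_table: pd.DataFrame,
    regressor: Regressor,
    outcome: str = "median_rt",
    level: str = "participant",
) -> pd.DataFrame | FitResult:
    """Fit a simple regression of a per-pair statistic on a regressor.

    ``stats_table`` is a pair-stats frame (participant_id, value_small,
    value_large, error_rate, median_rt_ms). At ``level="participant"`` one
    fit per participant is returned as a DataFrame; at ``level="group"`` the
    pair statistics are first averaged across participants and a single
    FitResult is returned. R^2 is the squared Pearson correlation of the
    fitted line with the observations.
    """
    if outcome not in OUTCOME_COLUMNS:
        raise ValueError(f"outcome must be one of {sorted(OUTCOME_COLUMNS)}")
    col = OUTCOME_COLUMNS[outcome]
    df = stats_table.copy()
    df["x"] = [
        regressor[(s, l)] for s, l in zip(df["value_small"], df["value_large"])
    ]
    if level == "group":
        cell = df.groupby(["value_small", "value_large"], sort=True).agg(
            x=("x", "first"), y=(col, "mean")
        )
        if len(cell) < 3:
            raise ValueError("need at least 3 distinct pairs")
        slope, intercept, r2 = _simple_fit(cell["x"].to_numpy(), cell["y"].to_numpy())
        return FitResult("group", regressor.kind, outcome, slope, intercept, r2)
    if level != "participant":
        raise ValueError(f"level must be 'participant' or 'group', got {level!r}")
    rows = []
    for pid, grp in df.groupby("participant_id", sort=True):
        if grp[["value_small", "value_large"]].drop_duplicates().shape[0] < 3:
            raise ValueError(f"participant {pid}: fewer than 3 distinct pairs")
        slope, intercept, r2 = _simple_fit(grp["x"].to_numpy(), grp[col].to_numpy())
        rows.append(
            {
                "participant_id": pid,
                "kind": regressor.kind,
                "outcome": outcome,
                "slope": slope,
                "intercept": intercept,
                "r_squared": r2,
            }
        )
    return pd.DataFrame(rows)


def scale_invariance_check(
    stats_table: pd.DataFrame,
    value_set: ValueSet | Sequence[int],
    outcome: str = "median_rt",
    scale: int = 5,
    tol: float = 1e-10,
) -> Dict[str, float | bool]:
    """Verify the ln(c)-shift identity of the value-distance regressor.

    Fits the value-distance effect on the given statistics twice: on the
    original value set and on the set multiplied by ``scale`` (with the pair
    labels rescaled accordingly). Slope and R^2 must agree to ``tol`` and
    the intercepts differ by slope * ln(scale).
    """
    if not isinstance(value_set, ValueSet):
        value_set = ValueSet(value_set)
    reg = make_regressor("value_distance", value_set)
    fit = fit_effect(stats_table, reg, outcome=outcome, level="group")

    scaled_set = ValueSet([v * scale for v in value_set])
    scaled_stats = stats_table.copy()
    scaled_stats["value_small"] = scaled_stats["value_small"] * scale
    scaled_stats["value_large"] = scaled_stats["value_large"] * scale
    reg_s = make_regressor("value_distance", scaled_set)
    fit_s = fit_effect(scaled_stats, reg_s, outcome=outcome, level="group")

    slope_dev = abs(fit.slope - fit_s.slope)
    r2_dev = abs(fit.r_squared - fit_s.r_squared)
    shift_dev = abs((fit.intercept - fit_s.intercept) - fit.slope * np.log(scale))
    return {
        "slope": fit.slope,
        "slope_scaled": fit_s.slope,
        "r_squared": fit.r_squared,
        "r_squared_scaled": fit_s.r_squared,
        "intercept": fit.intercept,
        "intercept_scaled": fit_s.intercept,
        "slope_deviation": float(slope_dev),
        "r_squared_deviation": float(r2_dev),
        "intercept_shift_deviation": float(shift_dev),
        "passed": bool(slope_dev <= tol and r2_dev <= tol and shift_dev <= tol),
    }
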