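"""Trial-table I/O, per-pair aggregation, and participant exclusion rules.

The on-disk format is a UTF-8 comma-separated table with one row per trial:

    participant_id,condition,block,trial_index,left_value,right_value,
    response_side,correct,rt_ms

Aggregation follows the convention of computing, for every participant and
every unordered numerosity pair, the mean error rate and the median reaction
time over ALL trials of that pair -- correct and erroneous alike, with no
slow-outlier trimming (the median is robust to slow outliers).

Exclusion rules are stand-ins for informally stated criteria ("responded
randomly", "mixed up the response buttons", near-zero distance-effect fit,
extreme size-slope outlier); every threshold is a keyword argument with a
documented default.
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping, Sequence, Tuple

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "TRIAL_COLUMNS",
    "TrialSchemaError",
    "read_trials",
    "write_trials",
    "validate_trials",
    "pair_stats",
    "apply_exclusions",
]

TRIAL_COLUMNS: Tuple[str, ...] = (
    "participant_id",
    "condition",
    "block",
    "trial_index",
    "left_value",
    "right_value",
    "response_side",
    "correct",
    "rt_ms",
)

_BOOL_MAP = {
    "true": True, "false": False, "1": True, "0": False,
    True: True, False: False, 1: True, 0: False,
}


class TrialSchemaError(ValueError):
    """A trial table violates the schema; message lists offending rows."""


def _coerce_bool(series: pd.Series) -> pd.Series:
    def conv(x):
        key = x.strip().lower() if isinstance(x, str) else x
        if isinstance(key, (bool, np.bool_)):
            return bool(key)
        if key in _BOOL_MAP:
            return _BOOL_MAP[key]
        return None

    return series.map(conv)


def validate_trials(df: pd.DataFrame) -> pd.DataFrame:
    """Validate and coerce a trial table; raise TrialSchemaError on violations.

    Row numbers in error messages are 0-based positions in the table.
    """
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise TrialSchemaError(f"missing columns: {missing}")
    out = df.copy()
    problems = []
    for col in ("block", "trial_index", "left_value", "right_value", "rt_ms"):
        coerced = pd.to_numeric(out[col], errors="coerce")
        bad = out.index[coerced.isna()].tolist()
        if bad:
            problems.append(f"column {col!r}: non-numeric values at rows {bad[:10]}")
        out[col] = coerced
    correct = _coerce_bool(out["correct"])
    bad = out.index[correct.isna()].tolist()
    if bad:
        problems.append(f"column 'correct': non-boolean values at rows {bad[:10]}")
    if problems:
        raise TrialSchemaError("; ".join(problems))
    out["correct"] = correct.astype(bool)
    for col in ("block", "trial_index", "left_value", "right_value"):
        out[col] = out[col].astype(int)
    out["rt_ms"] = out["rt_ms"].astype(float)

    ties = out.index[out["left_value"] == out["right_value"]].tolist()
    if ties:
        raise TrialSchemaError(f"tie pairs (left == right) at rows {ties[:10]}")
    nonpos = out.index[out["rt_ms"] <= 0].tolist()
    if nonpos:
        raise TrialSchemaError(f"non-positive rt_ms at rows {nonpos[:10]}")
    bad_side = out.index[~out["response_side"].isin(["left", "right"])].tolist()
    if bad_side:
        raise TrialSchemaError(f"response_side not left/right at rows {bad_side[:10]}")
    larger = np.where(out["left_value"] > out["right_value"], "left", "right")
    implied = out["response_side"].to_numpy() == larger
    mismatch = out.index[implied != out["correct"].to_numpy()].tolist()
    if mismatch:
        raise TrialSchemaError(
            f"'correct' inconsistent with response_side/larger side at rows {mismatch[:10]}"
        )
    return out


def read_trials(path) -> pd.DataFrame:
    """Read and validate a trial CSV."""
    return validate_trials(pd.read_csv(path))


def write_trials(trials: pd.DataFrame, path) -> None:
    """Write a trial table to CSV (header row, no index)."""
    trials.to_csv(path, index=False, columns=list(TRIAL_COLUMNS))


def pair_stats(
    trials: pd.DataFrame, extra_by: Sequence[str] = ()
) -> pd.DataFrame:
    """Per-participant per-unordered-pair mean error rate and median RT.

    Both correct and erroneous trials enter both statistics; an even trial
    count gives the median as the mean of the two central order statistics.
    ``extra_by`` adds further grouping columns (e.g. ``["block"]``).
    """
    if len(trials) == 0:
        raise ValueError("empty trial table")
    df = trials.copy()
    df["value_small"] = df[["left_value", "right_value"]].min(axis=1)
    df["value_large"] = df[["left_value", "right_value"]].max(axis=1)
    keys = ["participant_id", *extra_by, "value_small", "value_large"]
    grouped = df.groupby(keys, sort=True)
    out = grouped.agg(
        n_trials=("correct", "size"),
        error_rate=("correct", lambda c: 1.0 - c.mean()),
        median_rt_ms=("rt_ms", "median"),
    ).reset_index()
    return out


def apply_exclusions(
    trials: pd.DataFrame,
    rt_distance_r2: Mapping[str, float] | pd.Series | None = None,
    size_slopes: pd.DataFrame | None = None,
    accuracy_threshold: float = 0.60,
    swap_threshold: float = 0.50,
    r2_threshold: float = 0.20,
    z_threshold: float = 3.5,
) -> pd.DataFrame:
    """Flag participants for exclusion.

    Rules (all thresholds configurable):

    (i)   overall accuracy below ``accuracy_threshold`` -> "random/swapped";
          additionally below ``swap_threshold`` -> "keys likely swapped"
          (below-chance accuracy suggests reversed response keys);
    (ii)  RT distance-effect fit R^2 below ``r2_threshold`` (pass the
          per-participant R^2 values via ``rt_distance_r2``);
    (iii) size-effect slope an extreme outlier within its condition:
          leave-one-out |z| above ``z_threshold`` (pass a frame with
          participant_id, condition, slope via ``size_slopes``). The z-score
          standardizes each slope against the mean and SD of the *other*
          participants in the condition, so a single extreme value cannot
          mask itself.

    Returns a frame with participant_id, excluded, reasons (list of
    "label (statistic)" strings; empty iff not excluded).
    """
    acc = trials.groupby("participant_id")["correct"].mean()
    reasons: dict[str, list[str]] = {pid: [] for pid in acc.index}
    for pid, a in acc.items():
        if a < accuracy_threshold:
            label = "random/swapped" if a >= swap_threshold else "keys likely swapped"
            reasons[pid].append(f"{label} (accuracy={a:.3f})")
    if rt_distance_r2 is not None:
        for pid, r2 in dict(rt_distance_r2).items():
            if pid in reasons and r2 < r2_threshold:
                reasons[pid].append(f"flat RT distance fit (R2={r2:.3f})")
    if size_slopes is not None:
        for _, grp in size_slopes.groupby("condition"):
            slopes = grp["slope"].to_numpy(float)
            if len(slopes) < 3:
                continue
            for i, (_, row) in enumerate(grp.iterrows()):
                others = np.delete(slopes, i)
                sd = others.std(ddof=1)
                if sd == 0:
                    continue
                z = (slopes[i] - others.mean()) / sd
                if abs(z) > z_threshold and row["participant_id"] in reasons:
                    reasons[row["participant_id"]].append(
                        f"size-slope outlier (|z|={abs(z):.1f})"
                    )
    records = []
    for pid in sorted(reasons):
        excluded = bool(reasons[pid])
        if excluded:
            logger.info("excluding %s: %s", pid, "; ".join(reasons[pid]))
        records.append(
            {"participant_id": pid, "excluded": excluded, "reasons": reasons[pid]}
        )
    return pd.DataFrame.from_records(records)
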