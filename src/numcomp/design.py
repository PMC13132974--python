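"""Stimulus designs for nonsymbolic numerosity comparison experiments.

Two designs are covered: an omitted-range design over the numerosities
{5, 10, 15, 35, 40, 45} (which manipulates the association between values and
the "smaller"/"larger" response categories while keeping frequencies uniform),
and a frequency-manipulated design over multiples of 5 from 5 to 45 in which
the base token frequency of each numerosity follows an everyday (power-law
like), uniform, or reversed-everyday distribution.

Trial templates enumerate ordered pairs (left, right) with a multiplicity:
under a frequency table f, the ordered pair (i, j) with i != j appears
f(i) * f(j) * repeats times, so the total trial count is
repeats * ((sum f)^2 - sum f^2).

The module also computes the association statistics a design induces -- for
each value, the proportion of its presentations in which it is the smaller
(or larger) member of the pair -- and generates dot-array stimulus geometry
(random non-overlapping dot placement inside a square field measured in
degrees of visual angle, with a luminance-uninformative black/white split).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Sequence, Tuple

import numpy as np
import pandas as pd

__all__ = [
    "STUDY1_VALUES",
    "STUDY2_VALUES",
    "EVERYDAY_FREQUENCIES",
    "CONDITIONS",
    "ValueSet",
    "FrequencyTable",
    "TrialTemplate",
    "DesignSpec",
    "DotArraySpec",
    "build_frequency_table",
    "build_trial_templates",
    "build_study1_design",
    "association_statistics",
    "order_map",
    "generate_dot_array",
]

#: Omitted-range value set: multiples of 5 in [5, 45] minus {20, 25, 30}.
STUDY1_VALUES: Tuple[int, ...] = (5, 10, 15, 35, 40, 45)

#: Full value set for the frequency-manipulated design.
STUDY2_VALUES: Tuple[int, ...] = (5, 10, 15, 20, 25, 30, 35, 40, 45)

#: Everyday base token frequencies (value: tokens). These printed counts are
#: the ground truth of the design; the motivating frequency ~ 10/initial-value
#: rule does not reproduce them under any single rounding convention, so the
#: table itself is hard-coded.
EVERYDAY_FREQUENCIES: Dict[int, int] = {
    5: 10, 10: 5, 15: 4, 20: 3, 25: 2, 30: 2, 35: 2, 40: 2, 45: 1,
}

CONDITIONS: Tuple[str, ...] = ("everyday", "uniform", "reversed_everyday", "study1")


@dataclass(frozen=True)
class ValueSet:
    """An ordered set of distinct positive integer numerosities."""

    values: Tuple[int, ...]

    def __init__(self, values: Sequence[int]) -> None:
        vals = tuple(int(v) for v in values)
        if len(vals) == 0:
            raise ValueError("empty value set")
        if any(v <= 0 for v in vals):
            raise ValueError(f"values must be positive integers, got {vals}")
        if any(b <= a for a, b in zip(vals, vals[1:])):
            raise ValueError(f"values must be strictly increasing, got {vals}")
        object.__setattr__(self, "values", vals)

    def __len__(self) -> int:
        return len(self.values)

    def __iter__(self):
        return iter(self.values)

    def __contains__(self, v: int) -> bool:
        return v in self.values


@dataclass(frozen=True)
class FrequencyTable:
    """Base token frequencies f(v) for one condition's value set."""

    condition: str
    value_set: ValueSet
    base_frequency: Mapping[int, int]

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise ValueError(
                f"unknown condition {self.condition!r}; expected one of {CONDITIONS}"
            )
        for v, f in self.base_frequency.items():
            if v not in self.value_set:
                raise ValueError(f"frequency key {v} not in value set")
            if f < 1:
                raise ValueError(f"frequency of {v} must be >= 1, got {f}")
        missing = [v for v in self.value_set if v not in self.base_frequency]
        if missing:
            raise ValueError(f"values without a frequency: {missing}")

    def total_tokens(self) -> int:
        return sum(self.base_frequency.values())


@dataclass(frozen=True)
class TrialTemplate:
    """One ordered (left, right) numerosity pair with a presentation count."""

    left_value: int
    right_value: int
    multiplicity: int

    def __post_init__(self) -> None:
        if self.left_value == self.right_value:
            raise ValueError(f"tie pair ({self.left_value}, {self.right_value})")
        if self.multiplicity < 1:
            raise ValueError(f"multiplicity must be >= 1, got {self.multiplicity}")


@dataclass(frozen=True)
class DesignSpec:
    """A full session design: value set, frequencies, templates, trial order."""

    value_set: ValueSet
    frequency_table: FrequencyTable
    templates: Tuple[TrialTemplate, ...]
    total_trials: int
    seed: int = 0

    def __post_init__(self) -> None:
        if self.total_trials != sum(t.multiplicity for t in self.templates):
            raise ValueError("total_trials does not equal the sum of multiplicities")
        mult = {(t.left_value, t.right_value): t.multiplicity for t in self.templates}
        for (i, j), m in mult.items():
            if mult.get((j, i)) != m:
                raise ValueError(f"asymmetric multiplicity for pair ({i}, {j})")

    @property
    def condition(self) -> str:
        return self.frequency_table.condition

    def trial_sequence(self, seed: int | None = None) -> List[Tuple[int, int]]:
        """Expanded (left, right) trial list, uniformly shuffled.

        The shuffle is an unconstrained uniform permutation seeded by
        ``seed`` (defaults to the spec's own seed).
        """
        pairs = [
            (t.left_value, t.right_value)
            for t in self.templates
            for _ in range(t.multiplicity)
        ]
        rng = np.random.default_rng(self.seed if seed is None else seed)
        order = rng.permutation(len(pairs))
        return [pairs[i] for i in order]

    def to_frame(self, seed: int | None = None) -> pd.DataFrame:
        """Trial list in the trial-table CSV schema with empty response fields."""
        seq = self.trial_sequence(seed)
        n = len(seq)
        block = 1 + (4 * np.arange(n)) // n
        return pd.DataFrame(
            {
                "participant_id": "",
                "condition": self.condition,
                "block": block,
                "trial_index": np.arange(n),
                "left_value": [p[0] for p in seq],
                "right_value": [p[1] for p in seq],
                "response_side": "",
                "correct": "",
                "rt_ms": "",
            }
        )

    def to_json(self) -> str:
        return json.dumps(
            {
                "condition": self.condition,
                "values": list(self.value_set.values),
                "base_frequency": {
                    str(v): int(f)
                    for v, f in sorted(self.frequency_table.base_frequency.items())
                },
                "templates": [
                    [t.left_value, t.right_value, t.multiplicity]
                    for t in self.templates
                ],
                "total_trials": self.total_trials,
                "seed": self.seed,
            },
            sort_keys=True,
        )


def build_frequency_table(condition: str, value_set: ValueSet | Sequence[int]) -> FrequencyTable:
    """Return the base frequency table for a condition.

    ``everyday`` and ``reversed_everyday`` use the printed token counts (the
    reversed table is the everyday count sequence mirrored over the sorted
    values); ``uniform`` and ``study1`` assign every value one token.
    """
    if not isinstance(value_set, ValueSet):
        value_set = ValueSet(value_set)
    if condition not in CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}; expected one of {CONDITIONS}")
    if condition in ("everyday", "reversed_everyday", "uniform"):
        if value_set.values != STUDY2_VALUES:
            raise ValueError(
                f"condition {condition!r} requires the canonical 9-value set "
                f"{STUDY2_VALUES}, got {value_set.values}"
            )
    elif value_set.values != STUDY1_VALUES:
        raise ValueError(
            f"condition 'study1' requires the canonical 6-value set "
            f"{STUDY1_VALUES}, got {value_set.values}"
        )

    if condition == "everyday":
        freqs = dict(EVERYDAY_FREQUENCIES)
    elif condition == "reversed_everyday":
        counts = [EVERYDAY_FREQUENCIES[v] for v in STUDY2_VALUES]
        freqs = dict(zip(STUDY2_VALUES, reversed(counts)))
    else:
        freqs = {v: 1 for v in value_set}
    return FrequencyTable(condition=condition, value_set=value_set, base_frequency=freqs)


def build_trial_templates(
    table: FrequencyTable, repeats: int, seed: int = 0
) -> DesignSpec:
    """Expand a frequency table into ordered-pair trial templates.

    Every ordered pair (i, j), i != j, gets multiplicity
    f(i) * f(j) * repeats; for a uniform table this reduces to ``repeats``
    per ordered pair.
    """
    if repeats < 1:
        raise ValueError(f"repeats must be >= 1, got {repeats}")
    values = table.value_set.values
    if len(values) < 2:
        raise ValueError("need at least 2 values to form pairs")
    f = table.base_frequency
    templates = tuple(
        TrialTemplate(i, j, f[i] * f[j] * repeats)
        for i in values
        for j in values
        if i != j
    )
    total = sum(t.multiplicity for t in templates)
    return DesignSpec(
        value_set=table.value_set,
        frequency_table=table,
        templates=templates,
        total_trials=total,
        seed=seed,
    )


def build_study1_design(repeats: int = 20, seed: int = 0) -> DesignSpec:
    """Omitted-range design: all 30 ordered pairs of {5,10,15,35,40,45}.

    With the default 20 repeats this is a 600-trial session.
    """
    table = build_frequency_table("study1", ValueSet(STUDY1_VALUES))
    return build_trial_templates(table, repeats, seed=seed)


def association_statistics(spec: DesignSpec) -> Dict[int, Tuple[float, float]]:
    """Per-value (p_smaller, p_larger) proportions induced by the design.

    p_larger(v) is the multiplicity-weighted fraction of trials containing v
    in which v is the larger member. For a uniform design this reduces to
    (rank - 1) / (m - 1) with ascending 1-based ranks, e.g. 8 among 1..9 is
    the larger member 87.5% of the time.
    """
    larger: Dict[int, int] = {v: 0 for v in spec.value_set}
    total: Dict[int, int] = {v: 0 for v in spec.value_set}
    for t in spec.templates:
        big = max(t.left_value, t.right_value)
        for v in (t.left_value, t.right_value):
            total[v] += t.multiplicity
            if v == big:
                larger[v] += t.multiplicity
    out: Dict[int, Tuple[float, float]] = {}
    for v in spec.value_set:
        if total[v] == 0:
            raise ValueError(f"value {v} absent from all trials")
        p_larger = larger[v] / total[v]
        out[v] = (1.0 - p_larger, p_larger)
    return out


def order_map(value_set: ValueSet | Sequence[int]) -> Dict[int, int]:
    """Rank (1-based, ascending) of each value in its set."""
    if not isinstance(value_set, ValueSet):
        value_set = ValueSet(value_set)  # validates distinctness/order
    return {v: i + 1 for i, v in enumerate(value_set.values)}


@dataclass(frozen=True)
class DotArraySpec:
    """Geometry of one dot-array stimulus (degrees of visual angle)."""

    n_dots: int
    positions: Tuple[Tuple[float, float], ...]
    colors: Tuple[str, ...]
    field_size_deg: float = 2.0
    dot_diameter_deg: float = 0.2

    def __post_init__(self) -> None:
        if len(self.positions) != self.n_dots or len(self.colors) != self.n_dots:
            raise ValueError("positions/colors length must equal n_dots")
        n_black = sum(c == "black" for c in self.colors)
        if abs(2 * n_black - self.n_dots) > 1:
            raise ValueError("black/white counts must differ by at most 1")

    def convex_hull_area(self) -> float:
        """Area of the convex hull of the dot centers (0 for n < 3)."""
        if self.n_dots < 3:
            return 0.0
        from scipy.spatial import ConvexHull

        return float(ConvexHull(np.asarray(self.positions)).volume)

    def density(self) -> float:
        """Dots per square degree of field area."""
        return self.n_dots / self.field_size_deg**2

    def to_json(self) -> str:
        return json.dumps(
            {
                "n_dots": self.n_dots,
                "positions": [[round(x, 6), round(y, 6)] for x, y in self.positions],
                "colors": list(self.colors),
                "field_size_deg": self.field_size_deg,
                "dot_diameter_deg": self.dot_diameter_deg,
            },
            sort_keys=True,
        )


def generate_dot_array(
    n: int,
    rng: np.random.Generator | int,
    field_size_deg: float = 2.0,
    dot_diameter_deg: float = 0.2,
    max_attempts: int = 10_000,
) -> DotArraySpec:
    """Place n non-overlapping dots uniformly at random inside the field.

    Dot centers are kept a radius away from the field edge so every dot lies
    fully inside, and at least one diameter apart so no two dots overlap
    (rejection sampling, ``max_attempts`` draws per dot). Half the dots are
    black and half white (the extra dot of an odd count going to black is
    decided by the shuffled assignment), so total luminance carries no
    numerosity information.
    """
    if n <= 0:
        raise ValueError(f"n must be positive, got {n}")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    r = dot_diameter_deg / 2.0
    lo, hi = r, field_size_deg - r
    if hi <= lo:
        raise ValueError("field too small for a single dot")
    positions: List[Tuple[float, float]] = []
    pts = np.empty((0, 2))
    for _ in range(n):
        for attempt in range(max_attempts):
            p = rng.uniform(lo, hi, size=2)
            if pts.size == 0 or np.all(
                np.hypot(*(pts - p).T) >= dot_diameter_deg
            ):
                positions.append((float(p[0]), float(p[1])))
                pts = np.vstack([pts, p])
                break
        else:
            raise RuntimeError(
                f"could not place dot {len(positions) + 1}/{n} after "
                f"{max_attempts} attempts; field too crowded"
            )
    colors = ["black"] * math.ceil(n / 2) + ["white"] * (n // 2)
    rng.shuffle(colors)
    return DotArraySpec(
        n_dots=n,
        positions=tuple(positions),
        colors=tuple(colors),
        field_size_deg=field_size_deg,
        dot_diameter_deg=dot_diameter_deg,
    )
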