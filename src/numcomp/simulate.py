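"""Synthetic trial generators for numerosity comparison.

Two generative accounts are implemented, mirroring the two candidate
explanations of comparison performance:

* A psychophysical (ratio-driven) generator: each trial is a two-boundary
  Wiener diffusion whose drift is proportional to the log ratio of the two
  numerosities, v = k * ln(large/small). Stimulus frequency may be coupled
  multiplicatively to the threshold, the nondecision time, and/or the drift,
  with an optional geometric block-wise decay of the coupling -- the
  machinery needed to emulate frequency-induced size-effect changes and
  their fading over a session.

* A statistics-driven (association/frequency) generator: mean RT and error
  probability are linear/logistic in a log-distance term and a sum-of-
  reciprocals size term, computed either on the values themselves or on
  their ranks in the session's ordered set ("order" basis). This emulates
  performance governed by stimulus statistics rather than magnitudes.

Expected-performance grids for both accounts (the arbitrary-unit difficulty
surfaces over the pair space) are also provided:

    ANS difficulty(pair) = a * ln(large / (large - small)) + b
    DSS difficulty(pair) = a1 * (large - small) + a2 * (1/x1 + 1/x2) + b

The diffusion simulator integrates dX = v dt + s dW with an Euler step of
dt = 1 ms and noise scaling s = 0.1, starting unbiased at a/2 between
absorbing boundaries {0, a}. Within-step boundary crossings are resolved by
exact Brownian-bridge absorption sampling (the crossing probability given
the step's endpoints is exp(-2 d0 d1 / (s^2 dt)) and does not depend on the
drift), which removes the O(sqrt(dt)) first-passage bias of naive Euler;
the simulator matches the analytic accuracy 1/(1+exp(-v a/s^2)) and mean
decision time (a/2v) tanh(v a/2 s^2).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Mapping, Tuple

import numpy as np
import pandas as pd
from scipy.special import expit

from .design import DesignSpec, FrequencyTable, ValueSet

__all__ = [
    "GridParams",
    "DDMParams",
    "FrequencyCoupling",
    "CohortSpec",
    "DSSGenParams",
    "ans_expected_grid",
    "dss_expected_grid",
    "pair_frequency",
    "wiener_first_passage",
    "simulate_ddm_trial",
    "simulate_ans_cohort",
    "simulate_dss_cohort",
]

#: Lower clamp on the coupled threshold, as a fraction of the baseline.
MIN_THRESHOLD_FRACTION = 0.2


@dataclass(frozen=True)
class GridParams:
    """Free parameters of the expected-performance grid formulas."""

    a: float = 1.0    # ratio-effect scale
    b: float = 0.0    # offset
    a1: float = 0.4   # linear distance weight (statistics-based grid)
    a2: float = 1.0   # reciprocal-sum size weight (statistics-based grid)


@dataclass(frozen=True)
class DDMParams:
    """Baseline diffusion parameters.

    k       drift per unit log-ratio (evidence/s); v = k * ln(large/small)
    a0      boundary separation (evidence units)
    ter0    nondecision time (s)
    s       diffusion noise, the fixed scaling constant (conventionally 0.1)

    The defaults produce session-level accuracy and latency in the range
    typical of adult numerosity comparison (group error rates around
    5-20% and median RTs around half a second, depending on the design).
    """

    k: float = 0.45
    a0: float = 0.1
    ter0: float = 0.35
    s: float = 0.1

    def __post_init__(self) -> None:
        if self.k < 0 or self.a0 <= 0 or self.ter0 < 0 or self.s <= 0:
            raise ValueError(f"invalid diffusion parameters {self}")


@dataclass(frozen=True)
class FrequencyCoupling:
    """Multiplicative coupling of pair frequency to diffusion parameters.

    For a trial with normalized pair frequency phi in [0, 1], a reference
    frequency phi_ref, and block b (1-based), with
    g = gain * (phi - phi_ref) * block_decay**(b - 1):

        threshold:    a   -> a0   * (1 - g), clamped at 0.2 * a0
        nondecision:  ter -> ter0 * (1 - g), clamped at 0
        drift:        v   -> v * (1 + g)

    The cohort simulator uses the session's trial-weighted mean frequency
    as phi_ref, so the coupling encodes relative frequency within the
    session: pairs more frequent than the session average get a lower
    threshold (or shorter nondecision time, or higher drift), rarer pairs
    the opposite, and a uniform session is left at baseline. block_decay
    < 1 makes the frequency influence fade geometrically over the session;
    block_decay = 1 keeps it constant.
    """

    threshold_gain: float = 0.0
    nondecision_gain: float = 0.0
    drift_gain: float = 0.0
    block_decay: float = 1.0

    def __post_init__(self) -> None:
        for g in (self.threshold_gain, self.nondecision_gain, self.drift_gain):
            if not 0.0 <= g < 1.0:
                raise ValueError(f"coupling gains must lie in [0, 1), got {g}")
        if not 0.0 < self.block_decay <= 1.0:
            raise ValueError(f"block_decay must lie in (0, 1], got {self.block_decay}")


@dataclass(frozen=True)
class CohortSpec:
    """Size, heterogeneity and seed of a simulated participant cohort."""

    n_participants: int = 20
    heterogeneity_cv: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_participants < 1:
            raise ValueError("n_participants must be >= 1")
        if self.heterogeneity_cv < 0:
            raise ValueError("heterogeneity_cv must be >= 0")


@dataclass(frozen=True)
class DSSGenParams:
    """Mean structure of the statistics-driven generator.

    RT (s):    rt_base - rt_distance_weight * ln(d) + rt_size_weight * r
    error:     logistic(er_logit_intercept - er_distance_weight * ln(d)
                         + er_size_weight * r)

    where d is the basis distance (value difference, or rank difference on
    the "order" basis) and r = rarity(x1) + rarity(x2) is a frequency-driven
    size term with rarity(v) = 1 - f(v)/max f taken from the session's base
    frequency table: under this account the size effect comes from stimulus
    frequency, so a uniform-frequency session produces none (r constant at
    0) while an everyday table makes rare large values slow and error-prone
    and a reversed table the opposite. Gaussian RT noise, truncated at 1 ms.
    """

    rt_base: float = 0.45
    rt_distance_weight: float = 0.06
    rt_size_weight: float = 0.06
    rt_noise_sd: float = 0.08
    er_logit_intercept: float = -1.2
    er_distance_weight: float = 1.0
    er_size_weight: float = 0.5

    def __post_init__(self) -> None:
        if self.rt_noise_sd < 0:
            raise ValueError("rt_noise_sd must be >= 0")


# ---------------------------------------------------------------------------
# Expected-performance grids


def ans_expected_grid(
    value_set: ValueSet, params: GridParams = GridParams()
) -> Dict[Tuple[int, int], float]:
    """Ratio-driven difficulty a*ln(large/distance)+b per unordered pair."""
    out: Dict[Tuple[int, int], float] = {}
    vals = value_set.values if isinstance(value_set, ValueSet) else tuple(value_set)
    for i, small in enumerate(vals):
        for large in vals[i + 1 :]:
            if large == small:
                raise ValueError(f"tie pair ({small}, {large})")
            out[(small, large)] = params.a * np.log(large / (large - small)) + params.b
    return out


def dss_expected_grid(
    value_set: ValueSet, params: GridParams = GridParams()
) -> Dict[Tuple[int, int], float]:
    """Statistics-driven difficulty a1*distance + a2*(1/x1+1/x2) + b."""
    out: Dict[Tuple[int, int], float] = {}
    vals = value_set.values if isinstance(value_set, ValueSet) else tuple(value_set)
    if any(v == 0 for v in vals):
        raise ValueError("zero value in value set")
    for i, small in enumerate(vals):
        for large in vals[i + 1 :]:
            out[(small, large)] = (
                params.a1 * (large - small)
                + params.a2 * (1.0 / small + 1.0 / large)
                + params.b
            )
    return out


# ---------------------------------------------------------------------------
# Pair frequency


def pair_frequency(table: FrequencyTable) -> Dict[Tuple[int, int], float]:
    """Normalized per-pair frequency phi in (0, 1].

    phi(x1, x2) = (f(x1) + f(x2)) / max over pairs, mirroring the additive
    structure of the size regressor; invariant to rescaling all base
    frequencies by a constant. Keys are ordered pairs (both orders).
    """
    f = table.base_frequency
    vals = table.value_set.values
    raw = {
        (i, j): f[i] + f[j] for i in vals for j in vals if i != j
    }
    top = max(raw.values())
    return {p: w / top for p, w in raw.items()}


# ---------------------------------------------------------------------------
# Diffusion simulator


def wiener_first_passage(
    v: np.ndarray,
    a: np.ndarray,
    ter: np.ndarray,
    rng: np.random.Generator,
    dt: float = 0.001,
    s: float = 0.1,
    max_t: float = 10.0,
) -> Tuple[np.ndarray, np.ndarray]:
    """Vectorized first-passage simulation of a batch of diffusion trials.

    Each trial starts at a/2 between absorbing boundaries {0, a} and evolves
    by Euler steps x += v dt + s sqrt(dt) N(0,1); within-step crossings are
    resolved by Brownian-bridge absorption sampling. Returns
    (correct, rt) where ``correct`` marks absorption at the upper boundary
    and rt = decision time + ter. Trials still running at ``max_t`` are
    absorbed toward the nearer boundary.
    """
    v, a, ter = np.broadcast_arrays(
        np.atleast_1d(np.asarray(v, float)),
        np.atleast_1d(np.asarray(a, float)),
        np.atleast_1d(np.asarray(ter, float)),
    )
    if np.any(a <= 0):
        raise ValueError("non-positive boundary separation")
    n = v.shape[0]
    x = a / 2.0
    t = np.zeros(n)
    correct = np.zeros(n, dtype=bool)
    rt = np.zeros(n)
    alive = np.arange(n)
    step_sd = s * np.sqrt(dt)
    s2dt = s * s * dt
    while alive.size:
        x0 = x[alive]
        aa = a[alive]
        x1 = x0 + v[alive] * dt + step_sd * rng.standard_normal(alive.size)
        t[alive] += dt
        up = x1 >= aa
        down = x1 <= 0.0
        mid = ~(up | down)
        if mid.any():
            i = np.flatnonzero(mid)
            # exact bridge crossing probabilities given the step endpoints
            p_up = np.exp(-2.0 * (aa[i] - x0[i]) * (aa[i] - x1[i]) / s2dt)
            p_down = np.exp(-2.0 * x0[i] * x1[i] / s2dt)
            u = rng.random(i.size)
            hit_up = u < p_up
            hit_down = (~hit_up) & (u < p_up + p_down)
            up[i] |= hit_up
            down[i] |= hit_down
        timeout = t[alive] >= max_t
        done = up | down | timeout
        if done.any():
            idx = alive[done]
            correct[idx] = up[done] | (timeout & ~up & ~down)[done] & (
                x1[done] > aa[done] / 2.0
            )
            rt[idx] = t[idx] + ter[idx]
        x[alive] = x1
        alive = alive[~done]
    return correct, rt


def _effective_parameters(
    ddm_k: np.ndarray,
    ddm_a0: np.ndarray,
    ddm_ter0: np.ndarray,
    log_ratio: np.ndarray,
    phi: np.ndarray,
    block: np.ndarray,
    coupling: FrequencyCoupling,
    phi_reference: float = 0.0,
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    decay = coupling.block_decay ** (block - 1)
    rel = phi - phi_reference
    g_thr = coupling.threshold_gain * rel * decay
    g_ter = coupling.nondecision_gain * rel * decay
    g_v = coupling.drift_gain * rel * decay
    a = ddm_a0 * np.clip(1.0 - g_thr, MIN_THRESHOLD_FRACTION, None)
    ter = np.clip(ddm_ter0 * (1.0 - g_ter), 0.0, None)
    v = ddm_k * log_ratio * (1.0 + g_v)
    return v, a, ter


def simulate_ddm_trial(
    pair: Tuple[int, int],
    block: int,
    ddm: DDMParams,
    coupling: FrequencyCoupling,
    phi: float,
    rng: np.random.Generator | int,
    phi_reference: float = 0.0,
) -> Tuple[str, float]:
    """Simulate one comparison trial; returns (choice, rt in seconds).

    ``choice`` is "larger" when the accumulator is absorbed at the correct
    (larger-side) boundary and "smaller" otherwise. With the default
    ``phi_reference = 0`` the coupling acts on the absolute pair frequency;
    pass the session mean to reproduce the cohort simulator's relative
    coupling.
    """
    x1, x2 = pair
    if x1 == x2:
        raise ValueError(f"tie pair {pair}")
    if not 0.0 <= phi <= 1.0:
        raise ValueError(f"phi must lie in [0, 1], got {phi}")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    large, small = max(x1, x2), min(x1, x2)
    v, a, ter = _effective_parameters(
        np.array([ddm.k]),
        np.array([ddm.a0]),
        np.array([ddm.ter0]),
        np.array([np.log(large / small)]),
        np.array([float(phi)]),
        np.array([block]),
        coupling,
        phi_reference=phi_reference,
    )
    correct, rt = wiener_first_passage(v, a, ter, rng, s=ddm.s)
    return ("larger" if correct[0] else "smaller"), float(rt[0])


def _participant_multipliers(
    rng: np.random.Generator, cv: float, n: int
) -> np.ndarray:
    """Mean-one log-normal multipliers with coefficient of variation cv."""
    if cv == 0:
        return np.ones((n, 3))
    sigma = np.sqrt(np.log1p(cv * cv))
    return rng.lognormal(mean=-sigma * sigma / 2.0, sigma=sigma, size=(n, 3))


def _trial_frame(
    participant_id: str,
    condition: str,
    seq: list,
    block: np.ndarray,
    correct: np.ndarray,
    rt_s: np.ndarray,
) -> pd.DataFrame:
    left = np.array([p[0] for p in seq])
    right = np.array([p[1] for p in seq])
    larger_side = np.where(left > right, "left", "right")
    other_side = np.where(left > right, "right", "left")
    return pd.DataFrame(
        {
            "participant_id": participant_id,
            "condition": condition,
            "block": block,
            "trial_index": np.arange(len(seq)),
            "left_value": left,
            "right_value": right,
            "response_side": np.where(correct, larger_side, other_side),
            "correct": correct.astype(bool),
            # round half up to integer milliseconds
            "rt_ms": np.floor(rt_s * 1000.0 + 0.5).astype(int),
        }
    )


def simulate_ans_cohort(
    spec: DesignSpec,
    cohort: CohortSpec,
    ddm: DDMParams = DDMParams(),
    coupling: FrequencyCoupling = FrequencyCoupling(),
) -> pd.DataFrame:
    """Simulate a cohort of diffusion-driven participants on a design.

    Each participant runs the full design in an independently shuffled
    order; per-participant (k, a0, ter0) are jittered by independent mean-one
    log-normal multipliers with coefficient of variation
    ``cohort.heterogeneity_cv``. Blocks are contiguous quarters of each
    participant's presentation order. Bit-reproducible given
    (spec, cohort.seed).
    """
    master = np.random.default_rng(cohort.seed)
    mult = _participant_multipliers(master, cohort.heterogeneity_cv, cohort.n_participants)
    phi_map = pair_frequency(spec.frequency_table)
    # session mean frequency, weighted by template multiplicity
    phi_ref = sum(
        phi_map[(t.left_value, t.right_value)] * t.multiplicity for t in spec.templates
    ) / spec.total_trials
    frames = []
    for p in range(cohort.n_participants):
        rng = np.random.default_rng(master.integers(2**31))
        seq = spec.trial_sequence(seed=int(rng.integers(2**31)))
        n = len(seq)
        block = 1 + (4 * np.arange(n)) // n
        log_ratio = np.array([np.log(max(a, b) / min(a, b)) for a, b in seq])
        phi = np.array([phi_map[p_] for p_ in seq])
        k_p, a_p, t_p = ddm.k * mult[p, 0], ddm.a0 * mult[p, 1], ddm.ter0 * mult[p, 2]
        v, a, ter = _effective_parameters(
            k_p, a_p, t_p, log_ratio, phi, block, coupling, phi_reference=phi_ref
        )
        correct, rt = wiener_first_passage(v, a, ter, rng, s=ddm.s)
        frames.append(
            _trial_frame(f"p{p + 1:03d}", spec.condition, seq, block, correct, rt)
        )
    return pd.concat(frames, ignore_index=True)


def simulate_dss_cohort(
    spec: DesignSpec,
    cohort: CohortSpec,
    params: DSSGenParams = DSSGenParams(),
    basis: str = "value",
) -> pd.DataFrame:
    """Simulate a cohort whose performance follows stimulus statistics.

    With ``basis="value"`` the distance and size terms are computed on the
    numerosities themselves; with ``basis="order"`` on their ranks in the
    session's ordered value set -- the pattern expected when performance is
    governed by association statistics rather than magnitudes.
    """
    if basis not in ("value", "order"):
        raise ValueError(f"basis must be 'value' or 'order', got {basis!r}")
    ranks = {v: i + 1 for i, v in enumerate(spec.value_set.values)}
    freq = spec.frequency_table.base_frequency
    f_max = max(freq.values())
    rarity = {v: 1.0 - freq[v] / f_max for v in spec.value_set}
    master = np.random.default_rng(cohort.seed)
    frames = []
    for p in range(cohort.n_participants):
        rng = np.random.default_rng(master.integers(2**31))
        seq = spec.trial_sequence(seed=int(rng.integers(2**31)))
        n = len(seq)
        block = 1 + (4 * np.arange(n)) // n
        b1 = np.array([ranks[a] if basis == "order" else a for a, _ in seq], float)
        b2 = np.array([ranks[b] if basis == "order" else b for _, b in seq], float)
        dist = np.abs(b1 - b2)
        size = np.array([rarity[a] + rarity[b] for a, b in seq])
        mean_rt = (
            params.rt_base
            - params.rt_distance_weight * np.log(dist)
            + params.rt_size_weight * size
        )
        p_err = expit(
            params.er_logit_intercept
            - params.er_distance_weight * np.log(dist)
            + params.er_size_weight * size
        )
        if not np.all(np.isfinite(mean_rt)):
            raise ValueError("non-finite RT mean structure")
        rt = mean_rt + params.rt_noise_sd * rng.standard_normal(n)
        rt = np.clip(rt, 0.001, None)
        correct = rng.random(n) >= p_err
        frames.append(
            _trial_frame(f"p{p + 1:03d}", spec.condition, seq, block, correct, rt)
        )
    return pd.concat(frames, ignore_index=True)
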