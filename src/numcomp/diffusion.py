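"""EZ-diffusion parameter recovery and qualitative signature attribution.

The EZ method inverts three summary statistics of a condition's responses --
proportion correct Pc, variance of correct RTs VRT, and mean correct RT
MRT -- into the three core diffusion parameters (drift v, boundary
separation a, nondecision time Ter) in closed form, with noise scaling s:

    L   = ln(Pc / (1 - Pc))
    v   = sign(Pc - 1/2) * s * [L (L Pc^2 - L Pc + Pc - 1/2) / VRT]^(1/4)
    a   = s^2 L / v
    MDT = (a / 2v) * (1 - e^(-va/s^2)) / (1 + e^(-va/s^2))
    Ter = MRT - MDT

``ez_forward`` is the exact inverse (generating Pc, VRT, MRT from an
estimate), so fit(forward(theta)) = theta to numerical precision.

Qualitative attribution: changes in each diffusion parameter leave a
characteristic joint signature on speed and precision -- a drift increase
makes responses faster AND more precise; a threshold increase slower and
(slightly) more precise; a nondecision increase slower with unchanged
precision. ``classify_signature`` maps an observed (RT change, error-rate
change) pattern to the compatible parameter changes; in particular, faster
responses with unchanged-or-worse precision indicate a threshold and/or
nondecision DEcrease and exclude a drift account.

``frequency_diffusion_report`` applies this to a trial table: pairs are
binned by their normalized session frequency phi, EZ estimates are computed
per stratum (flagged with a bias warning when strata have unequal trial
counts, which they necessarily do under a frequency manipulation), and the
signature verdict is derived from high-minus-low-frequency behavioral
deltas. Because in a frequency-manipulated design phi is confounded with
pair difficulty (frequent pairs also tend to be easy), the behavioral
deltas feeding the classifier are difficulty-adjusted first: mean RT is
residualized on a quadratic in ln(ratio) and the error rate on a
trial-level logistic fit in ln(ratio) -- the shape the ratio effect itself
predicts -- so that only frequency-linked deviations remain. Effects
smaller than max(floor, z * jackknife SE over participants) count as
"none". The stratum EZ point estimates are reported raw.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, FrozenSet, List, Optional, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps

from .design import FrequencyTable
from .simulate import pair_frequency

__all__ = [
    "EZInputs",
    "DiffusionEstimate",
    "SignatureVerdict",
    "ez_forward",
    "ez_fit",
    "ez_fit_trials",
    "edge_correct",
    "classify_signature",
    "frequency_diffusion_report",
]


@dataclass(frozen=True)
class EZInputs:
    """Summary statistics entering the EZ inversion (seconds, s^2)."""

    pc: float
    vrt: float
    mrt: float
    n_trials: int
    edge_corrected: bool = False

    def __post_init__(self) -> None:
        if not 0.0 < self.pc < 1.0:
            raise ValueError(f"pc must lie strictly in (0, 1), got {self.pc}")
        if self.vrt <= 0 or self.mrt <= 0:
            raise ValueError("vrt and mrt must be positive")


@dataclass(frozen=True)
class DiffusionEstimate:
    """Recovered (drift, threshold, nondecision) with noise scaling s."""

    v: float
    a: float
    ter: float
    s: float = 0.1

    def __post_init__(self) -> None:
        if self.a <= 0:
            raise ValueError(f"threshold must be positive, got {self.a}")


@dataclass(frozen=True)
class SignatureVerdict:
    rt_effect: str                      # faster | slower | none
    er_effect: str                      # more_precise | less_precise | none
    attribution: FrozenSet[str]         # subset of {drift, threshold, nondecision}
    direction: str                      # increase | decrease | none
    rationale: str


def ez_forward(estimate: DiffusionEstimate) -> EZInputs:
    """Predicted (Pc, VRT, MRT) for a diffusion parameter triple."""
    v, a, s = estimate.v, estimate.a, estimate.s
    if v == 0:
        raise ValueError("v = 0: accuracy is exactly 1/2 and the logit is undefined")
    y = -v * a / (s * s)
    pc = 1.0 / (1.0 + np.exp(y))
    mdt = (a / (2.0 * v)) * (1.0 - np.exp(y)) / (1.0 + np.exp(y))
    L = np.log(pc / (1.0 - pc))
    vrt = s**4 * L * (L * pc**2 - L * pc + pc - 0.5) / v**4
    return EZInputs(pc=float(pc), vrt=float(vrt), mrt=float(mdt + estimate.ter), n_trials=0)


def ez_fit(inputs: EZInputs, s: float = 0.1) -> DiffusionEstimate:
    """Closed-form EZ inversion of (Pc, VRT, MRT).

    Pc exactly 1/2 is degenerate (the drift sign is undefined); callers
    should jitter an edge case toward 1 - 1/(2n) / 1/(2n) first (see
    ``edge_correct``).
    """
    pc = inputs.pc
    if pc == 0.5:
        raise ValueError(
            "pc = 0.5 exactly: drift direction undefined; add edge jitter "
            "(e.g. pc +- 1/(2 n_trials)) before fitting"
        )
    L = np.log(pc / (1.0 - pc))
    x = L * (L * pc**2 - L * pc + pc - 0.5) / inputs.vrt
    v = float(np.sign(pc - 0.5) * s * x**0.25)
    a = float(s * s * L / v)
    y = -v * a / (s * s)
    mdt = (a / (2.0 * v)) * (1.0 - np.exp(y)) / (1.0 + np.exp(y))
    return DiffusionEstimate(v=v, a=a, ter=float(inputs.mrt - mdt), s=s)


def edge_correct(pc: float, n_trials: int) -> Tuple[float, bool]:
    """Pull a perfect 0/1 accuracy inside (0,1) by half a trial's worth."""
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1 to edge-correct")
    if pc >= 1.0:
        return 1.0 - 1.0 / (2.0 * n_trials), True
    if pc <= 0.0:
        return 1.0 / (2.0 * n_trials), True
    return pc, False


def ez_fit_trials(correct: np.ndarray, rt_s: np.ndarray, s: float = 0.1) -> Tuple[DiffusionEstimate, EZInputs]:
    """EZ estimate from raw trial vectors (RT in seconds)."""
    correct = np.asarray(correct, bool)
    rt_s = np.asarray(rt_s, float)
    n = len(correct)
    if n < 2 or correct.sum() < 2:
        raise ValueError("need at least 2 correct trials")
    pc, flagged = edge_correct(correct.mean(), n)
    rts = rt_s[correct]
    inputs = EZInputs(
        pc=pc,
        vrt=float(rts.var(ddof=1)),
        mrt=float(rts.mean()),
        n_trials=n,
        edge_corrected=flagged,
    )
    return ez_fit(inputs, s=s), inputs


_SIGNATURE_MAP: Dict[Tuple[str, str], Tuple[FrozenSet[str], str, str]] = {
    ("faster", "more_precise"): (
        frozenset({"drift"}), "increase",
        "faster and more precise responses are the signature of a higher drift rate",
    ),
    ("faster", "less_precise"): (
        frozenset({"threshold", "nondecision"}), "decrease",
        "faster but less precise responses indicate a lowered threshold "
        "(and possibly shorter nondecision time); a drift change is excluded",
    ),
    ("faster", "none"): (
        frozenset({"threshold", "nondecision"}), "decrease",
        "faster responses without a reliable precision change indicate a "
        "lowered threshold and/or shorter nondecision time; drift is excluded",
    ),
    ("slower", "more_precise"): (
        frozenset({"threshold"}), "increase",
        "slower and more precise responses are the signature of a raised threshold",
    ),
    ("slower", "none"): (
        frozenset({"nondecision"}), "increase",
        "slower responses with unchanged precision indicate a longer nondecision time",
    ),
    ("slower", "less_precise"): (
        frozenset({"drift"}), "decrease",
        "slower and less precise responses are the signature of a lower drift rate",
    ),
    ("none", "more_precise"): (
        frozenset({"drift", "threshold"}), "increase",
        "ambiguous: higher precision without an RT change is compatible with "
        "offsetting drift and threshold increases",
    ),
    ("none", "less_precise"): (
        frozenset({"drift", "threshold"}), "decrease",
        "ambiguous: lower precision without an RT change is compatible with "
        "offsetting drift and threshold decreases",
    ),
    ("none", "none"): (frozenset(), "none", "no reliable change in either measure"),
}


def classify_signature(
    delta_rt: float,
    delta_er: float,
    rt_threshold: float = 0.015,
    er_threshold: float = 0.02,
) -> SignatureVerdict:
    """Map behavioral deltas (condition of interest minus reference) to
    compatible diffusion-parameter changes.

    ``delta_rt`` in seconds, ``delta_er`` in error-rate proportion; effects
    smaller than the thresholds count as "none".
    """
    if not np.isfinite(delta_rt) or not np.isfinite(delta_er):
        raise ValueError("missing or non-finite effect estimates")
    rt_effect = (
        "faster" if delta_rt < -rt_threshold
        else "slower" if delta_rt > rt_threshold
        else "none"
    )
    er_effect = (
        "more_precise" if delta_er < -er_threshold
        else "less_precise" if delta_er > er_threshold
        else "none"
    )
    attribution, direction, rationale = _SIGNATURE_MAP[(rt_effect, er_effect)]
    return SignatureVerdict(rt_effect, er_effect, attribution, direction, rationale)


def _adjusted_phi_deltas(df: pd.DataFrame) -> Tuple[float, float]:
    """High-minus-low frequency-stratum deltas of difficulty-adjusted
    mean RT (s) and error rate.

    Mean RT is residualized against a trial-count-weighted quadratic in
    ln(ratio); the error rate against a trial-level logistic fit in
    ln(ratio) (the functional form the ratio effect itself predicts, so
    its saturation at easy pairs does not leak into the frequency
    contrast).
    """
    import statsmodels.api as sm

    X = sm.add_constant(df["log_ratio"])
    glm = sm.GLM(
        (~df["correct"].astype(bool)).astype(float), X, family=sm.families.Binomial()
    ).fit()
    df = df.assign(er_pred=glm.predict(X))

    per_pair = (
        df.groupby(["value_small", "value_large", "stratum"])
        .agg(
            n=("correct", "size"),
            er=("correct", lambda c: 1.0 - c.mean()),
            er_pred=("er_pred", "first"),
            mrt=("rt_ms", lambda r: r.mean() / 1000.0),
            log_ratio=("log_ratio", "first"),
        )
        .reset_index()
    )
    lnr = per_pair["log_ratio"].to_numpy()
    design = np.column_stack([np.ones(len(per_pair)), lnr, lnr**2])
    w = np.sqrt(per_pair["n"].to_numpy(float))
    beta, *_ = np.linalg.lstsq(
        design * w[:, None], per_pair["mrt"].to_numpy() * w, rcond=None
    )
    per_pair["mrt_resid"] = per_pair["mrt"] - design @ beta
    per_pair["er_resid"] = per_pair["er"] - per_pair["er_pred"]

    hi, lo = per_pair["stratum"].max(), per_pair["stratum"].min()

    def _wmean(stratum, col: str) -> float:
        sub = per_pair[per_pair["stratum"] == stratum]
        return float(np.average(sub[col], weights=sub["n"]))

    return (
        _wmean(hi, "mrt_resid") - _wmean(lo, "mrt_resid"),
        _wmean(hi, "er_resid") - _wmean(lo, "er_resid"),
    )


def frequency_diffusion_report(
    trials: pd.DataFrame,
    frequency_table: FrequencyTable,
    n_strata: int = 3,
    rt_floor: float = 0.005,
    er_floor: float = 0.005,
    se_multiplier: float = 2.0,
    s: float = 0.1,
) -> Dict:
    """Per-frequency-stratum EZ estimates and a signature verdict.

    Pairs are binned into ``n_strata`` quantile strata of phi (terciles by
    default). EZ parameters are estimated from the pooled trials of each
    stratum. The verdict compares the highest against the lowest stratum
    on difficulty-adjusted mean RT and error rate (see
    ``_adjusted_phi_deltas``); an effect counts as present only when it
    exceeds max(floor, se_multiplier * jackknife SE), where the SE comes
    from leave-one-participant-out recomputation of the deltas.
    """
    df = trials.copy()
    df["value_small"] = df[["left_value", "right_value"]].min(axis=1)
    df["value_large"] = df[["left_value", "right_value"]].max(axis=1)
    df["log_ratio"] = np.log(df["value_large"] / df["value_small"])
    phi_map = pair_frequency(frequency_table)
    df["phi"] = [
        phi_map[(s_, l_)] for s_, l_ in zip(df["value_small"], df["value_large"])
    ]
    pair_phi = (
        df.groupby(["value_small", "value_large"])["phi"].first().reset_index()
    )
    if pair_phi["phi"].nunique() < 2:
        raise ValueError(
            "fewer than 2 distinct pair frequencies: cannot form strata "
            "(uniform designs carry no frequency signal)"
        )
    try:
        pair_phi["stratum"] = pd.qcut(
            pair_phi["phi"], q=n_strata, labels=False, duplicates="drop"
        )
    except ValueError as err:
        raise ValueError(f"could not form frequency strata: {err}") from err
    if pair_phi["stratum"].nunique() < 2:
        raise ValueError("frequency binning collapsed to a single stratum")
    df = df.merge(pair_phi, on=["value_small", "value_large"], suffixes=("", "_pair"))

    strata_rows = []
    warnings: List[str] = []
    for stratum, grp in df.groupby("stratum", sort=True):
        est, inputs = ez_fit_trials(
            grp["correct"].to_numpy(bool), grp["rt_ms"].to_numpy(float) / 1000.0, s=s
        )
        strata_rows.append(
            {
                "stratum": int(stratum),
                "phi_mean": float(grp["phi"].mean()),
                "n_trials": int(len(grp)),
                "pc": inputs.pc,
                "mrt_s": inputs.mrt,
                "vrt_s2": inputs.vrt,
                "v": est.v,
                "a": est.a,
                "ter": est.ter,
                "edge_corrected": inputs.edge_corrected,
            }
        )
    strata = pd.DataFrame(strata_rows)
    if strata["n_trials"].nunique() > 1:
        warnings.append(
            "unequal trial counts across frequency strata: quantitative EZ "
            "estimates may be biased; rely on the qualitative verdict"
        )

    delta_rt, delta_er = _adjusted_phi_deltas(df)

    participants = df["participant_id"].unique()
    if len(participants) >= 3:
        jack = np.array(
            [
                _adjusted_phi_deltas(df[df["participant_id"] != pid])
                for pid in participants
            ]
        )
        n_p = len(participants)
        se_rt, se_er = np.sqrt((n_p - 1) / n_p * ((jack - jack.mean(0)) ** 2).sum(0))
    else:
        se_rt = se_er = 0.0
    rt_threshold = max(rt_floor, se_multiplier * float(se_rt))
    er_threshold = max(er_floor, se_multiplier * float(se_er))
    verdict = classify_signature(
        delta_rt, delta_er, rt_threshold=rt_threshold, er_threshold=er_threshold
    )
    return {
        "strata": strata,
        "delta_rt_s": float(delta_rt),
        "delta_error_rate": float(delta_er),
        "rt_threshold": rt_threshold,
        "er_threshold": er_threshold,
        "verdict": verdict,
        "warnings": warnings,
    }
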