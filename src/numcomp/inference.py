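"""Study-level hypothesis tests and the sample-size computation.

Four pieces of machinery:

* A paired Wilcoxon signed-rank contrast of per-participant R^2 values from
  two competing regressors (value-based vs association-based), treating R^2
  as a repeated-measures ordinal variable.
* A between-condition contrast of per-participant effect slopes: a
  Shapiro-Wilk gate chooses one-way ANOVA (with omega-squared) when all
  groups look normal and Kruskal-Wallis (with the rank epsilon-squared
  analogue and Dunn's pairwise post hoc) otherwise.
* A block-wise slope analysis: per-participant slopes in contiguous session
  quarters, compared with a 4 (block, within) x k (condition, between)
  mixed ANOVA plus a Tukey post hoc on blocks.
* The minimal total N for a one-way fixed-effects ANOVA to reach a target
  power at effect size f, from the noncentral-F power function with
  noncentrality f^2 * N. The default allocation is balanced (total N a
  multiple of the group count), matching the convention of standard power
  software; ``allocation="any"`` sweeps every integer N.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Dict, Optional

import numpy as np
import pandas as pd
from scipy import stats

from .effects import Regressor, fit_effect
from .io_aggregate import pair_stats

__all__ = [
    "ContrastResult",
    "study1_model_contrast",
    "study2_slope_contrast",
    "block_slopes",
    "block_slope_analysis",
    "dunn_posthoc",
    "required_n_oneway_anova",
]


@dataclass
class ContrastResult:
    name: str
    statistic: float
    p_value: float
    effect_size: Optional[float] = None
    effect_size_label: Optional[str] = None
    posthoc: Optional[pd.DataFrame] = None
    details: Dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (np.isnan(self.p_value) or 0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p value out of [0, 1]: {self.p_value}")


def study1_model_contrast(
    fits_value: pd.DataFrame,
    fits_assoc: pd.DataFrame,
    alpha: float = 0.05,
) -> ContrastResult:
    """Paired Wilcoxon signed-rank test on per-participant R^2 pairs.

    Two-sided; zero differences are dropped; the exact null distribution is
    used for up to 25 informative pairs, the normal approximation with
    continuity correction beyond. The direction label reports which model
    fits better ("value_dominant" / "association_dominant") when the test
    is significant at ``alpha``, else "undecided".
    """
    merged = fits_value.merge(
        fits_assoc, on="participant_id", suffixes=("_value", "_assoc")
    )
    if len(merged) == 0:
        raise ValueError("no paired participants in the two fit sets")
    diff = merged["r_squared_value"].to_numpy() - merged["r_squared_assoc"].to_numpy()
    informative = diff[diff != 0]
    if len(informative) < 5:
        raise ValueError(
            f"only {len(informative)} nonzero R^2 differences; "
            "need at least 5 informative pairs for the signed-rank test"
        )
    method = "exact" if len(informative) <= 25 else "approx"
    res = stats.wilcoxon(
        informative,
        zero_method="wilcox",
        correction=(method == "approx"),
        alternative="two-sided",
        method=method,
    )
    med_v = float(np.median(merged["r_squared_value"]))
    med_a = float(np.median(merged["r_squared_assoc"]))
    if res.pvalue >= alpha:
        direction = "undecided"
    else:
        direction = "value_dominant" if med_v > med_a else "association_dominant"
    return ContrastResult(
        name="paired_wilcoxon_r2",
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        details={
            "median_r2_value": med_v,
            "median_r2_association": med_a,
            "n_pairs": int(len(merged)),
            "n_informative": int(len(informative)),
            "direction": direction,
            "method": method,
        },
    )


def _omega_squared(groups) -> float:
    """Omega-squared for a one-way between-subjects ANOVA."""
    k = len(groups)
    ns = np.array([len(g) for g in groups])
    n_total = ns.sum()
    grand = np.concatenate(groups).mean()
    ss_between = float(sum(n * (np.mean(g) - grand) ** 2 for n, g in zip(ns, groups)))
    ss_within = float(sum(((np.asarray(g) - np.mean(g)) ** 2).sum() for g in groups))
    ms_within = ss_within / (n_total - k)
    ss_total = ss_between + ss_within
    return (ss_between - (k - 1) * ms_within) / (ss_total + ms_within)


def dunn_posthoc(
    slopes: pd.DataFrame, value_col: str = "slope", adjust: str | None = None
) -> pd.DataFrame:
    """Dunn's rank-based pairwise post hoc after Kruskal-Wallis.

    Pooled ranks with tie correction; z_ij = (Rbar_i - Rbar_j) /
    sqrt((N(N+1)/12 - sum(t^3 - t)/(12(N-1))) * (1/n_i + 1/n_j)).
    ``adjust="holm"`` applies the Holm step-down correction; the default
    reports unadjusted two-sided p values.
    """
    df = slopes.copy()
    n_total = len(df)
    df["rank"] = df[value_col].rank()
    _, tie_counts = np.unique(df[value_col].to_numpy(), return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (12.0 * (n_total - 1))
    var_unit = n_total * (n_total + 1) / 12.0 - tie_term
    mean_ranks = df.groupby("condition")["rank"].mean()
    sizes = df.groupby("condition")["rank"].size()
    rows = []
    for g1, g2 in itertools.combinations(sorted(mean_ranks.index), 2):
        se = np.sqrt(var_unit * (1.0 / sizes[g1] + 1.0 / sizes[g2]))
        z = (mean_ranks[g1] - mean_ranks[g2]) / se
        p = 2.0 * stats.norm.sf(abs(z))
        rows.append({"group_1": g1, "group_2": g2, "z": float(z), "p_value": float(p)})
    out = pd.DataFrame(rows)
    if adjust == "holm":
        order = np.argsort(-np.abs(out["z"].to_numpy()))
        m = len(out)
        adj = np.empty(m)
        running_max = 0.0
        for rank_i, idx in enumerate(order):
            p_adj = min(1.0, (m - rank_i) * out.loc[idx, "p_value"])
            running_max = max(running_max, p_adj)
            adj[idx] = running_max
        out["p_adjusted"] = adj
    elif adjust is not None:
        raise ValueError(f"unknown adjustment {adjust!r}")
    return out


def study2_slope_contrast(
    slopes: pd.DataFrame,
    outcome_label: str = "slope",
    alpha_normality: float = 0.05,
    dunn_adjust: str | None = None,
) -> ContrastResult:
    """Compare per-participant slopes between conditions.

    A Shapiro-Wilk test per condition (at ``alpha_normality``) gates the
    omnibus: one-way ANOVA (F, omega-squared) when every group is
    compatible with normality, Kruskal-Wallis (chi-squared, rank
    epsilon-squared) with Dunn pairwise post hoc otherwise. Groups with
    fewer than 3 observations cannot be Shapiro-tested and route to the
    rank-based branch.
    """
    groups = {
        cond: grp["slope"].to_numpy(float)
        for cond, grp in slopes.groupby("condition", sort=True)
    }
    if len(groups) < 2:
        raise ValueError("need at least 2 conditions")
    for cond, g in groups.items():
        if len(g) < 2:
            raise ValueError(f"condition {cond!r} has fewer than 2 participants")
    normality = {}
    all_normal = True
    for cond, g in groups.items():
        if len(g) < 3:
            normality[cond] = np.nan
            all_normal = False
        else:
            p = float(stats.shapiro(g).pvalue)
            normality[cond] = p
            all_normal &= p >= alpha_normality
    arrays = list(groups.values())
    n_total = sum(len(g) for g in arrays)
    if all_normal:
        f_stat, p = stats.f_oneway(*arrays)
        return ContrastResult(
            name=f"one_way_anova[{outcome_label}]",
            statistic=float(f_stat),
            p_value=float(p),
            effect_size=float(_omega_squared(arrays)),
            effect_size_label="omega_squared",
            details={"normality_p": normality, "n": n_total},
        )
    h_stat, p = stats.kruskal(*arrays)
    posthoc = dunn_posthoc(slopes, adjust=dunn_adjust) if len(groups) >= 3 else None
    return ContrastResult(
        name=f"kruskal_wallis[{outcome_label}]",
        statistic=float(h_stat),
        p_value=float(p),
        # rank-based analogue of omega-squared; labelled explicitly
        effect_size=float(h_stat / (n_total - 1)),
        effect_size_label="rank_epsilon_squared",
        posthoc=posthoc,
        details={"normality_p": normality, "n": n_total},
    )


def block_slopes(
    trials: pd.DataFrame, regressor: Regressor, outcome: str = "median_rt"
) -> pd.DataFrame:
    """Per-participant per-block slope of a regressor on pair statistics."""
    stats_by_block = pair_stats(trials, extra_by=["block"])
    cond = trials.groupby("participant_id")["condition"].first()
    rows = []
    for block, grp in stats_by_block.groupby("block", sort=True):
        fits = fit_effect(grp, regressor, outcome=outcome, level="participant")
        for _, r in fits.iterrows():
            rows.append(
                {
                    "participant_id": r["participant_id"],
                    "condition": cond[r["participant_id"]],
                    "block": int(block),
                    "slope": r["slope"],
                }
            )
    return pd.DataFrame(rows)


def block_slope_analysis(
    trials: pd.DataFrame, regressor: Regressor, outcome: str = "median_rt"
) -> Dict:
    """Block x condition mixed ANOVA on per-block effect slopes.

    Blocks are the contiguous session quarters recorded in the trial table.
    Returns the per-participant-per-block slopes, the mixed ANOVA table
    (block within, condition between; no sphericity correction), and a
    Tukey HSD post hoc on blocks. Requires at least two conditions for the
    interaction to be defined.
    """
    import pingouin as pg
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    slopes = block_slopes(trials, regressor, outcome=outcome)
    if slopes["block"].nunique() < 2:
        raise ValueError("need at least 2 blocks")
    if slopes["condition"].nunique() < 2:
        raise ValueError(
            "single-condition input: the block x condition interaction is undefined"
        )
    aov = pg.mixed_anova(
        data=slopes,
        dv="slope",
        within="block",
        subject="participant_id",
        between="condition",
        correction=False,
    )
    tukey = pairwise_tukeyhsd(slopes["slope"], slopes["block"].astype(str))
    tukey_df = pd.DataFrame(
        tukey.summary().data[1:], columns=tukey.summary().data[0]
    )

    def _row(source: str) -> Dict[str, float]:
        r = aov.loc[aov["Source"] == source].iloc[0]
        p_col = "p_unc" if "p_unc" in aov.columns else "p-unc"
        return {"F": float(r["F"]), "p": float(r[p_col]),
                "df1": float(r["DF1"]), "df2": float(r["DF2"])}

    return {
        "slopes": slopes,
        "anova": aov,
        "block_effect": _row("block"),
        "condition_effect": _row("condition"),
        "interaction": _row("Interaction"),
        "tukey_blocks": tukey_df,
    }


def oneway_anova_power(n_total: int, f: float, alpha: float, k_groups: int) -> float:
    """Power of the one-way fixed-effects ANOVA omnibus F test.

    Noncentrality lambda = f^2 * N with numerator df k-1 and denominator
    df N-k.
    """
    if n_total <= k_groups:
        return 0.0
    df1, df2 = k_groups - 1, n_total - k_groups
    crit = stats.f.ppf(1.0 - alpha, df1, df2)
    return float(stats.ncf.sf(crit, df1, df2, f * f * n_total))


def required_n_oneway_anova(
    f: float,
    alpha: float = 0.05,
    power: float = 0.95,
    k_groups: int = 3,
    allocation: str = "balanced",
    max_n: int = 100_000,
) -> int:
    """Smallest total N reaching the target power.

    ``allocation="balanced"`` (default) considers only totals divisible by
    the number of groups -- the convention of standard power software, which
    assumes equal group sizes; ``allocation="any"`` sweeps every integer.
    """
    if f <= 0:
        raise ValueError("effect size f must be positive")
    if not 0 < alpha < 1 or not 0 < power < 1:
        raise ValueError("alpha and power must lie in (0, 1)")
    if k_groups < 2:
        raise ValueError("need at least 2 groups")
    if allocation not in ("balanced", "any"):
        raise ValueError(f"allocation must be 'balanced' or 'any', got {allocation!r}")
    step = k_groups if allocation == "balanced" else 1
    start = 2 * k_groups if allocation == "balanced" else k_groups + 1
    for n in range(start, max_n + 1, step):
        if oneway_anova_power(n, f, alpha, k_groups) >= power:
            return n
    raise ValueError(f"target power not attainable with N <= {max_n}")
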