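"""Study-level contrasts, post hoc machinery, and power analysis."""

import numpy as np
import pandas as pd
import pytest

import numcomp as nc
from numcomp.inference import dunn_posthoc, oneway_anova_power


def _fits(r2_values, pids=None):
    pids = pids or [f"p{i}" for i in range(len(r2_values))]
    return pd.DataFrame({"participant_id": pids, "r_squared": r2_values})


class TestModelContrast:
    def test_uniformly_better_model_gives_zero_statistic(self):
        rng = np.random.default_rng(1)
        assoc = rng.uniform(0.2, 0.4, 28)
        value = assoc + rng.uniform(0.05, 0.2, 28)
        res = nc.study1_model_contrast(_fits(value), _fits(assoc))
        assert res.statistic == 0.0
        assert res.p_value < 0.001
        assert res.details["direction"] == "value_dominant"

    def test_identical_fits_refused(self):
        fits = _fits(np.linspace(0.2, 0.6, 10))
        with pytest.raises(ValueError, match="informative"):
            nc.study1_model_contrast(fits, fits.copy())

    def test_antisymmetric_in_the_two_fit_sets(self):
        rng = np.random.default_rng(2)
        a = rng.uniform(0.2, 0.5, 20)
        b = a + rng.uniform(0.02, 0.3, 20)
        fwd = nc.study1_model_contrast(_fits(b), _fits(a))
        rev = nc.study1_model_contrast(_fits(a), _fits(b))
        assert fwd.p_value == pytest.approx(rev.p_value)
        assert fwd.details["direction"] == "value_dominant"
        assert rev.details["direction"] == "association_dominant"

    def test_large_samples_use_normal_approximation(self):
        rng = np.random.default_rng(3)
        a = rng.uniform(0.2, 0.5, 40)
        b = a + rng.normal(0.1, 0.05, 40)
        res = nc.study1_model_contrast(_fits(b), _fits(a))
        assert res.details["method"] == "approx"


def _slopes(groups):
    rows = []
    for cond, values in groups.items():
        for i, v in enumerate(values):
            rows.append(
                {"participant_id": f"{cond}_{i}", "condition": cond, "slope": v}
            )
    return pd.DataFrame(rows)


class TestSlopeContrast:
    def test_normal_groups_route_to_anova(self):
        rng = np.random.default_rng(4)
        slopes = _slopes(
            {
                "everyday": rng.normal(8, 1, 16),
                "uniform": rng.normal(5, 1, 24),
                "reversed_everyday": rng.normal(2, 1, 21),
            }
        )
        res = nc.study2_slope_contrast(slopes)
        assert res.name.startswith("one_way_anova")
        assert res.p_value < 1e-6
        assert res.effect_size_label == "omega_squared"
        assert res.effect_size > 0.5

    def test_skewed_groups_route_to_kruskal_with_dunn(self):
        rng = np.random.default_rng(5)
        slopes = _slopes(
            {
                "a": np.exp(rng.normal(2.0, 1.2, 18)),
                "b": np.exp(rng.normal(0.0, 1.2, 18)),
                "c": np.exp(rng.normal(0.0, 1.2, 18)),
            }
        )
        res = nc.study2_slope_contrast(slopes)
        assert res.name.startswith("kruskal_wallis")
        assert res.effect_size_label == "rank_epsilon_squared"
        assert res.posthoc is not None
        sig = res.posthoc.query("group_1 == 'a' and group_2 == 'b'")
        assert sig["p_value"].iloc[0] < 0.01

    def test_single_or_underpopulated_condition_rejected(self):
        with pytest.raises(ValueError):
            nc.study2_slope_contrast(_slopes({"a": [1.0, 2.0, 3.0]}))
        with pytest.raises(ValueError):
            nc.study2_slope_contrast(_slopes({"a": [1.0, 2.0], "b": [3.0]}))

    def test_null_rejection_rate_is_calibrated(self):
        rng = np.random.default_rng(6)
        rejections = 0
        n_reps = 300
        for _ in range(n_reps):
            slopes = _slopes(
                {c: np.exp(rng.normal(0, 0.8, 12)) for c in ("a", "b", "c")}
            )
            if nc.study2_slope_contrast(slopes).p_value < 0.05:
                rejections += 1
        assert 0.02 <= rejections / n_reps <= 0.09


class TestDunnPosthoc:
    def test_hand_computed_fixture_without_ties(self):
        slopes = _slopes({"a": [1, 2, 3], "b": [4, 5, 6], "c": [7, 8, 9]})
        out = dunn_posthoc(slopes).set_index(["group_1", "group_2"])
        # pooled ranks 1..9: mean ranks 2, 5, 8; var unit N(N+1)/12 = 7.5
        z_ab = (2 - 5) / np.sqrt(7.5 * (2 / 3))
        assert out.loc[("a", "b"), "z"] == pytest.approx(z_ab)
        assert out.loc[("a", "c"), "z"] == pytest.approx(2 * z_ab)

    def test_holm_adjustment_is_monotone_and_bounded(self):
        rng = np.random.default_rng(7)
        slopes = _slopes({c: rng.normal(i, 1, 10) for i, c in enumerate("abc")})
        out = dunn_posthoc(slopes, adjust="holm")
        assert (out["p_adjusted"] >= out["p_value"] - 1e-15).all()
        assert (out["p_adjusted"] <= 1.0).all()


class TestBlockAnalysis:
    def test_single_condition_interaction_undefined(self, small_ans_trials):
        reg = nc.make_regressor("size_sum", nc.ValueSet(nc.STUDY2_VALUES))
        with pytest.raises(ValueError, match="single-condition"):
            nc.block_slope_analysis(small_ans_trials, reg)

    def test_decaying_coupling_produces_block_by_condition_interaction(
        self, everyday_spec, reversed_spec
    ):
        cp = nc.FrequencyCoupling(threshold_gain=0.45, block_decay=0.5)
        frames = []
        for i, spec in enumerate((everyday_spec, reversed_spec)):
            tr = nc.simulate_ans_cohort(
                spec, nc.CohortSpec(n_participants=14, seed=21 + i), coupling=cp
            )
            tr["participant_id"] = spec.condition + "_" + tr["participant_id"]
            frames.append(tr)
        trials = pd.concat(frames, ignore_index=True)
        reg = nc.make_regressor("size_sum", nc.ValueSet(nc.STUDY2_VALUES))
        out = nc.block_slope_analysis(trials, reg)
        assert out["interaction"]["p"] < 0.05
        # the condition separation is largest in the first block
        sep = (
            out["slopes"]
            .groupby(["block", "condition"])["slope"]
            .mean()
            .unstack()
            .pipe(lambda d: d["everyday"] - d["reversed_everyday"])
        )
        assert sep.loc[1] == sep.max()


class TestPower:
    def test_balanced_allocation_matches_standard_power_software(self):
        assert nc.required_n_oneway_anova(0.64, 0.05, 0.95, 3) == 42
        # published benchmark of the same software convention
        assert nc.required_n_oneway_anova(0.25, 0.05, 0.80, 3) == 159

    def test_unconstrained_sweep_can_stop_one_short(self):
        assert nc.required_n_oneway_anova(0.64, 0.05, 0.95, 3, allocation="any") == 41

    def test_returned_n_is_minimal_against_direct_power_evaluation(self):
        for f in (0.40, 0.64):
            n = nc.required_n_oneway_anova(f, 0.05, 0.95, 3)
            assert oneway_anova_power(n, f, 0.05, 3) >= 0.95
            assert oneway_anova_power(n - 3, f, 0.05, 3) < 0.95

    def test_monotone_in_effect_size_and_alpha(self):
        base = nc.required_n_oneway_anova(0.4, 0.05, 0.95, 3)
        assert nc.required_n_oneway_anova(0.8, 0.05, 0.95, 3) <= base
        assert nc.required_n_oneway_anova(0.4, 0.01, 0.95, 3) >= base

    def test_power_increases_with_n(self):
        powers = [oneway_anova_power(n, 0.4, 0.05, 3) for n in range(9, 120, 3)]
        assert all(b > a for a, b in zip(powers, powers[1:]))

    def test_invalid_arguments_rejected(self):
        with pytest.raises(ValueError):
            nc.required_n_oneway_anova(0.0)
        with pytest.raises(ValueError):
            nc.required_n_oneway_anova(0.5, alpha=1.5)
        with pytest.raises(ValueError):
            nc.required_n_oneway_anova(0.5, k_groups=1)
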