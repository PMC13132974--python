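"""Design construction: frequency tables, trial combinatorics, association
statistics, and dot-array geometry."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import numcomp as nc
from numcomp.design import FrequencyTable, ValueSet


class TestValueSet:
    def test_rejects_duplicates_and_disorder(self):
        with pytest.raises(ValueError):
            ValueSet([5, 5, 10])
        with pytest.raises(ValueError):
            ValueSet([10, 5])
        with pytest.raises(ValueError):
            ValueSet([0, 5])

    def test_canonical_sets(self):
        assert nc.STUDY1_VALUES == (5, 10, 15, 35, 40, 45)
        assert len(nc.STUDY2_VALUES) == 9


class TestFrequencyTables:
    def test_everyday_counts_are_the_printed_table(self, study2_value_set):
        table = nc.build_frequency_table("everyday", study2_value_set)
        assert table.base_frequency == {
            5: 10, 10: 5, 15: 4, 20: 3, 25: 2, 30: 2, 35: 2, 40: 2, 45: 1
        }
        assert table.total_tokens() == 31

    def test_reversed_is_the_mirrored_count_sequence(self, study2_value_set):
        table = nc.build_frequency_table("reversed_everyday", study2_value_set)
        assert table.base_frequency == {
            5: 1, 10: 2, 15: 2, 20: 2, 25: 2, 30: 3, 35: 4, 40: 5, 45: 10
        }
        assert table.total_tokens() == 31

    @pytest.mark.parametrize("condition,values", [
        ("uniform", nc.STUDY2_VALUES), ("study1", nc.STUDY1_VALUES)
    ])
    def test_uniform_like_tables(self, condition, values):
        table = nc.build_frequency_table(condition, ValueSet(values))
        assert all(f == 1 for f in table.base_frequency.values())

    def test_unknown_condition_and_mismatched_set_rejected(self, study2_value_set):
        with pytest.raises(ValueError):
            nc.build_frequency_table("weekly", study2_value_set)
        with pytest.raises(ValueError):
            nc.build_frequency_table("everyday", ValueSet(nc.STUDY1_VALUES))
        with pytest.raises(ValueError):
            nc.build_frequency_table("study1", study2_value_set)


class TestTrialTemplates:
    def test_everyday_trial_counts(self, everyday_table):
        one = nc.build_trial_templates(everyday_table, repeats=1)
        two = nc.build_trial_templates(everyday_table, repeats=2)
        assert one.total_trials == 794
        assert two.total_trials == 1588
        mult = {(t.left_value, t.right_value): t.multiplicity for t in two.templates}
        assert mult[(5, 10)] == mult[(10, 5)] == 100
        assert mult[(40, 45)] == mult[(45, 40)] == 4

    def test_uniform_trial_count(self, uniform_spec):
        assert uniform_spec.total_trials == 1584

    def test_reversed_total_matches_everyday_by_symmetry(
        self, everyday_spec, reversed_spec
    ):
        assert reversed_spec.total_trials == everyday_spec.total_trials == 1588

    @given(
        st.lists(st.integers(1, 5), min_size=2, max_size=6).map(tuple),
    )
    def test_total_is_sum_squared_minus_sum_of_squares(self, counts):
        values = tuple(5 * (i + 1) for i in range(len(counts)))
        table = FrequencyTable("uniform", ValueSet(values), dict(zip(values, counts)))
        spec = nc.build_trial_templates(table, repeats=1)
        total_f = sum(counts)
        assert spec.total_trials == total_f**2 - sum(c * c for c in counts)

    def test_too_few_values_rejected(self):
        table = FrequencyTable("uniform", ValueSet([5]), {5: 1})
        with pytest.raises(ValueError):
            nc.build_trial_templates(table, repeats=1)


class TestStudy1Design:
    def test_default_is_600_trials_without_ties(self, study1_spec):
        assert study1_spec.total_trials == 600
        assert len(study1_spec.templates) == 30
        assert all(t.left_value != t.right_value for t in study1_spec.templates)

    def test_single_repeat_gives_30_trials(self):
        assert nc.build_study1_design(repeats=1).total_trials == 30

    def test_shuffle_is_seed_reproducible(self):
        a = nc.build_study1_design(repeats=2, seed=9).trial_sequence()
        b = nc.build_study1_design(repeats=2, seed=9).trial_sequence()
        c = nc.build_study1_design(repeats=2, seed=10).trial_sequence()
        assert a == b
        assert a != c


class TestAssociationStatistics:
    def test_study1_proportions_match_rank_fractions(self, study1_spec):
        stats = nc.association_statistics(study1_spec)
        p_smaller = [round(stats[v][0], 10) for v in nc.STUDY1_VALUES]
        assert p_smaller == [1.0, 0.8, 0.6, 0.4, 0.2, 0.0]

    def test_eight_among_one_to_nine_is_larger_seven_eighths(self):
        values = ValueSet(range(1, 10))
        table = FrequencyTable("uniform", values, {v: 1 for v in values})
        spec = nc.build_trial_templates(table, repeats=1)
        stats = nc.association_statistics(spec)
        assert stats[8][1] == pytest.approx(0.875)
        assert stats[9][1] == pytest.approx(1.0)

    def test_two_value_design_forces_extremes(self):
        values = ValueSet([7, 9])
        table = FrequencyTable("uniform", values, {7: 1, 9: 1})
        spec = nc.build_trial_templates(table, repeats=3)
        stats = nc.association_statistics(spec)
        assert stats[7] == (1.0, 0.0)
        assert stats[9] == (0.0, 1.0)

    @given(st.sets(st.integers(1, 60), min_size=3, max_size=8))
    def test_uniform_design_reduces_to_rank_fractions(self, value_pool):
        values = ValueSet(sorted(value_pool))
        table = FrequencyTable("uniform", values, {v: 1 for v in values})
        spec = nc.build_trial_templates(table, repeats=1)
        stats = nc.association_statistics(spec)
        m = len(values)
        for rank, v in enumerate(values, start=1):
            assert stats[v][1] == pytest.approx((rank - 1) / (m - 1))


class TestOrderMap:
    @pytest.mark.parametrize("values,value,rank", [
        ((1, 2, 3, 7, 8, 9), 7, 4),
        (nc.STUDY1_VALUES, 35, 4),
    ])
    def test_ranks(self, values, value, rank):
        assert nc.order_map(ValueSet(values))[value] == rank

    def test_consecutive_integers_rank_as_themselves(self):
        assert nc.order_map(ValueSet(range(1, 10))) == {v: v for v in range(1, 10)}


class TestDotArrays:
    def test_geometry_invariants_for_45_dots(self):
        spec = nc.generate_dot_array(45, rng=3)
        pts = np.asarray(spec.positions)
        assert pts.shape == (45, 2)
        assert pts.min() >= 0.1 - 1e-12 and pts.max() <= 1.9 + 1e-12
        diffs = pts[:, None, :] - pts[None, :, :]
        dists = np.hypot(diffs[..., 0], diffs[..., 1])
        np.fill_diagonal(dists, np.inf)
        assert dists.min() >= 0.2 - 1e-12

    def test_reproducible_given_seed(self):
        assert nc.generate_dot_array(30, rng=5).positions == \
            nc.generate_dot_array(30, rng=5).positions

    @pytest.mark.parametrize("n", [1, 2, 7, 44])
    def test_color_split_is_luminance_balanced(self, n):
        spec = nc.generate_dot_array(n, rng=1)
        n_black = sum(c == "black" for c in spec.colors)
        assert abs(n_black - (n - n_black)) <= 1

    def test_numerosity_correlates_retained(self):
        small = nc.generate_dot_array(5, rng=2)
        large = nc.generate_dot_array(45, rng=2)
        assert large.convex_hull_area() > small.convex_hull_area()
        assert large.density() > small.density()

    def test_overcrowded_field_raises(self):
        with pytest.raises((RuntimeError, ValueError)):
            nc.generate_dot_array(500, rng=0, max_attempts=200)

    def test_nonpositive_count_rejected(self):
        with pytest.raises(ValueError):
            nc.generate_dot_array(0, rng=0)
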