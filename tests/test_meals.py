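"""Tests for mixture fitting, the meal criterion, visit merging and post-meal deltas."""

import numpy as np
import pandas as pd
import pytest

from thermofeed import (
    CriterionError,
    DataError,
    MixtureFit,
    cow_post_meal_trait,
    fit_interval_mixture,
    largest_meal_per_day,
    meal_criterion,
    merge_visits_to_meals,
    post_meal_delta,
    simulate_visit_intervals,
    true_meal_criterion,
)

from conftest import make_trace

SYM_MIX = (0.5, 0.5, 0.25, 2.5, 0.25)


def visits_df(rows):
    return pd.DataFrame(rows, columns=["cow_id", "start", "end", "intake_kg"])


def visit(cow, start_min, end_min, kg, day="2022-06-01"):
    base = pd.Timestamp(day)
    return (cow, base + pd.Timedelta(minutes=start_min), base + pd.Timedelta(minutes=end_min), kg)


class TestMixtureFit:
    def test_recovers_known_components(self):
        iv = simulate_visit_intervals(SYM_MIX, 10_000, seed=2)
        fit = fit_interval_mixture(iv, seed=2)
        assert fit.converged
        assert abs(fit.means[0] - 0.5) < 0.05
        assert abs(fit.means[1] - 2.5) < 0.05

    def test_identical_intervals_flagged_unconverged(self):
        fit = fit_interval_mixture(np.full(100, 30.0), seed=0)
        assert not fit.converged
        with pytest.raises(CriterionError):
            meal_criterion(fit)

    def test_two_components_fit_at_least_as_well_as_one(self):
        iv = simulate_visit_intervals(SYM_MIX, 2000, seed=4)
        two = fit_interval_mixture(iv, n_components=2, seed=4)
        one = fit_interval_mixture(iv, n_components=1, seed=4)
        assert two.log_likelihood >= one.log_likelihood

    def test_nonpositive_interval_rejected(self):
        bad = np.concatenate([np.ones(60), [-1.0]])
        with pytest.raises(DataError):
            fit_interval_mixture(bad)

    def test_too_few_intervals_rejected(self):
        with pytest.raises(DataError):
            fit_interval_mixture(np.ones(10) * 5)


class TestMealCriterion:
    def test_symmetric_intersection_at_midpoint(self):
        fit = MixtureFit(
            weights=np.array([0.5, 0.5]), means=np.array([0.5, 2.5]),
            sds=np.array([0.25, 0.25]), log_likelihood=0.0, n_intervals=100, converged=True,
        )
        assert meal_criterion(fit) == pytest.approx(10**1.5, rel=1e-9)

    def test_matches_grid_search_oracle(self):
        mix = (0.6, 0.4, 0.3, 2.2, 0.4)
        fit = MixtureFit(
            weights=np.array([0.6, 0.4]), means=np.array([0.4, 2.2]),
            sds=np.array([0.3, 0.4]), log_likelihood=0.0, n_intervals=100, converged=True,
        )
        assert meal_criterion(fit) == pytest.approx(true_meal_criterion(mix), rel=1e-6)

    def test_dominated_component_raises(self):
        fit = MixtureFit(
            weights=np.array([1e-9, 1 - 1e-9]), means=np.array([1.0, 1.2]),
            sds=np.array([2.0, 2.0]), log_likelihood=0.0, n_intervals=100, converged=True,
        )
        with pytest.raises(CriterionError):
            meal_criterion(fit)


class TestMergeVisits:
    def test_gap_rule(self):
        v = visits_df([visit("a", 0, 10, 1.0), visit("a", 15, 20, 1.0), visit("a", 50, 60, 2.0)])
        meals = merge_visits_to_meals(v, 26.4)  # gaps 5 and 30 min
        assert len(meals) == 2
        assert meals.iloc[0]["n_visits"] == 2
        assert meals.iloc[0]["intake_kg"] == pytest.approx(2.0)

    def test_gap_exactly_at_criterion_not_merged(self):
        v = visits_df([visit("a", 0, 10, 1.0), visit("a", 36.4, 40, 1.0)])
        assert len(merge_visits_to_meals(v, 26.4)) == 2

    def test_single_visit_identity(self):
        v = visits_df([visit("a", 0, 10, 1.5)])
        meals = merge_visits_to_meals(v, 26.4)
        assert len(meals) == 1
        row = meals.iloc[0]
        assert row["start"] == v.iloc[0]["start"]
        assert row["end"] == v.iloc[0]["end"]
        assert row["intake_kg"] == pytest.approx(1.5)

    def test_overlapping_visits_rejected(self):
        v = visits_df([visit("a", 0, 10, 1.0), visit("a", 5, 12, 1.0)])
        with pytest.raises(DataError):
            merge_visits_to_meals(v, 26.4)

    def test_limit_criteria_and_intake_conservation(self, small_herd):
        visits = small_herd.visits
        tiny = merge_visits_to_meals(visits, 1e-9)
        assert len(tiny) == len(visits)  # one meal per visit
        huge = merge_visits_to_meals(visits, 1e9)
        assert len(huge) == visits["cow_id"].nunique()  # one block per cow
        for meals in (tiny, huge):
            assert meals["intake_kg"].sum() == pytest.approx(visits["intake_kg"].sum(), abs=1e-9)


class TestLargestMeal:
    def test_argmax_and_tie_break(self):
        v = visits_df(
            [visit("a", 0, 10, 3.0), visit("a", 60, 80, 5.0), visit("a", 200, 210, 2.0),
             visit("b", 0, 10, 4.0), visit("b", 100, 110, 4.0)]
        )
        meals = largest_meal_per_day(merge_visits_to_meals(v, 26.4))
        a = meals[(meals["cow_id"] == "a") & meals["is_largest_of_day"]]
        assert len(a) == 1 and a.iloc[0]["intake_kg"] == pytest.approx(5.0)
        b = meals[(meals["cow_id"] == "b") & meals["is_largest_of_day"]]
        assert len(b) == 1 and b.iloc[0]["start"].minute == 0  # tie -> earlier meal

    def test_one_flag_per_cow_day(self, small_herd):
        crit = small_herd.truth.meal_criterion_min
        meals = largest_meal_per_day(merge_visits_to_meals(small_herd.visits, crit))
        flags = meals[meals["is_largest_of_day"]].groupby(["cow_id", "date"]).size()
        per_day = meals.groupby(["cow_id", "date"]).size()
        assert (flags == 1).all()
        assert len(flags) == len(per_day)  # every cow-day with a meal has a flag


class TestPostMealDelta:
    def ramp_trace(self, slope_per_step=-0.01, n=288):
        return make_trace(38.7 + slope_per_step * np.arange(n))

    def test_constant_trace_zero_delta(self):
        tr = make_trace(np.full(288, 38.7))
        start = tr.times[100]
        d = post_meal_delta(tr, start, start + pd.Timedelta(minutes=30))
        assert d.delta == pytest.approx(0.0, abs=1e-12)

    def test_linear_ramp_hand_value(self):
        # 0.01 degC drop per 5-min step, 30-min meal aligned to the grid:
        # pre centre is 5 min before the start, post centre 20 min after the
        # end -> centres 55 min (11 steps) apart
        tr = self.ramp_trace()
        start = tr.times[40]
        d = post_meal_delta(tr, start, start + pd.Timedelta(minutes=30))
        assert d.delta == pytest.approx(-0.11, abs=1e-9)
        assert d.delta == pytest.approx(d.post_temp - d.pre_temp, abs=1e-12)

    def test_antisymmetric_under_value_reversal(self):
        tr = self.ramp_trace()
        rev = make_trace(tr.values[::-1].copy())
        start = tr.times[40]
        end = start + pd.Timedelta(minutes=30)
        assert post_meal_delta(rev, start, end).delta == pytest.approx(
            -post_meal_delta(tr, start, end).delta, abs=1e-9
        )

    def test_insufficient_coverage_skipped(self):
        tr = self.ramp_trace(n=12)  # one hour of records
        start = tr.times[1]  # fewer than 3 records before the start
        assert post_meal_delta(tr, start, start + pd.Timedelta(minutes=5)) is None
        late = tr.times[-1]  # post window runs off the end of the trace
        assert post_meal_delta(tr, late, late + pd.Timedelta(minutes=30)) is None

    def test_cow_trait_nan_when_no_meal_evaluable(self):
        tr = self.ramp_trace(n=12)
        meals = largest_meal_per_day(
            merge_visits_to_meals(visits_df([visit("cow", 0, 5, 1.0)]), 26.4)
        )
        with pytest.warns(UserWarning):
            trait, deltas = cow_post_meal_trait(tr, meals)
        assert np.isnan(trait) and deltas == []


def test_criterion_recovery_against_truth(small_herd):
    """Pooled-interval fit on simulated intervals lands near the analytic criterion."""
    mix = small_herd.config.meal_interval_mixture
    truth = true_meal_criterion(mix)
    iv = simulate_visit_intervals(mix, 10_000, seed=11)
    est = meal_criterion(fit_interval_mixture(iv, seed=11))
    assert est == pytest.approx(truth, rel=0.05)
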