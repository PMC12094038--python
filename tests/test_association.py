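"""Tests for trial regressions, daily mixed models, partial correlations and
the adjusted-R² model comparison."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy import stats

from thermofeed import (
    ModelError,
    compare_rfi_models,
    daily_mixed_model,
    partial_correlation,
    regress_trait,
)

from test_energy import synthetic_records


def trial_frame(n=300, slope=-2.5, seed=0, n_cohorts=4, n_stations=2, resid_sd=1.0):
    rng = np.random.default_rng(seed)
    cohort = rng.integers(0, n_cohorts, n)
    station = cohort % n_stations
    temp = 38.7 + rng.normal(0, 0.11, n)
    thi_cov = rng.normal(65, 4, n)  # varies within cohort
    cohort_eff = rng.normal(25, 2, n_cohorts)
    resp = cohort_eff[cohort] + slope * (temp - 38.7) + 0.05 * thi_cov + rng.normal(0, resid_sd, n)
    return pd.DataFrame(
        {
            "cow_id": [f"cow{i}" for i in range(n)],
            "response": resp,
            "temp_trait": temp,
            "cohort": [f"c{k}" for k in cohort],
            "station": [f"st{s}" for s in station],
            "thi": thi_cov,
        }
    )


class TestRegressTrait:
    def test_recovers_injected_slope(self):
        df = trial_frame(n=800, slope=-2.5, seed=1)
        res = regress_trait(df, "dmi", "mean_temp")
        assert abs(res.slope - (-2.5)) < 2 * res.se
        assert res.p_value < 0.05
        assert 0 < res.se

    def test_slope_invariant_to_thi_recentering(self):
        df = trial_frame(seed=2)
        res = regress_trait(df, "dmi", "mean_temp")
        shifted = df.assign(thi=df["thi"] - 65.0)
        res2 = regress_trait(shifted, "dmi", "mean_temp")
        assert res2.slope == pytest.approx(res.slope, abs=1e-9)
        assert res2.se == pytest.approx(res.se, abs=1e-9)

    def test_slope_invariant_to_cohort_relabelling(self):
        df = trial_frame(seed=3)
        relabel = {"c0": "zebra", "c1": "alpha", "c2": "mike", "c3": "kilo"}
        res = regress_trait(df, "dmi", "mean_temp")
        res2 = regress_trait(df.assign(cohort=df["cohort"].map(relabel)), "dmi", "mean_temp")
        assert res2.slope == pytest.approx(res.slope, abs=1e-9)

    def test_constant_temperature_trait_rejected(self):
        df = trial_frame(seed=4)
        df["temp_trait"] = 38.7
        with pytest.raises(ModelError):
            regress_trait(df, "dmi", "mean_temp")

    def test_single_station_interaction_aliased_not_fatal(self):
        df = trial_frame(seed=5, n_stations=1)
        res = regress_trait(df, "dmi", "mean_temp")
        assert np.isfinite(res.slope)


def daily_frame(n_cows=80, n_days=10, slope=-2.3, cow_sd=1.0, seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    cow_eff = rng.normal(0, cow_sd, n_cows)
    for i in range(n_cows):
        cohort = f"c{i % 4}"
        offsets = rng.normal(0, 0.05, n_days)
        for d in range(n_days):
            rows.append(
                {
                    "cow_id": f"cow{i}",
                    "cohort": cohort,
                    "temp_trait": 38.7 + offsets[d],
                    "response": 26 + cow_eff[i] + slope * offsets[d] + rng.normal(0, 0.5),
                }
            )
    return pd.DataFrame(rows)


class TestDailyMixedModel:
    def test_recovers_daily_slope(self):
        df = daily_frame(seed=1)
        res = daily_mixed_model(df, "daily_dmi", "daily_mean_temp")
        assert abs(res.slope - (-2.3)) < 2 * res.se

    def test_zero_between_cow_variance_matches_pooled_ols(self):
        df = daily_frame(cow_sd=0.0, seed=2)
        res = daily_mixed_model(df, "daily_dmi", "daily_mean_temp")
        X = sm.add_constant(
            pd.concat(
                [df["temp_trait"],
                 pd.get_dummies(df["cohort"], prefix="cohort", drop_first=True, dtype=float)],
                axis=1,
            )
        )
        ols_slope = sm.OLS(df["response"], X).fit().params["temp_trait"]
        assert res.slope == pytest.approx(ols_slope, abs=1e-3)

    def test_one_record_per_cow_falls_back_to_ols(self):
        df = daily_frame(n_days=1, seed=3)
        res = daily_mixed_model(df, "daily_dmi", "daily_mean_temp")
        X = sm.add_constant(
            pd.concat(
                [df["temp_trait"],
                 pd.get_dummies(df["cohort"], prefix="cohort", drop_first=True, dtype=float)],
                axis=1,
            )
        )
        ols_slope = sm.OLS(df["response"], X).fit().params["temp_trait"]
        assert res.slope == pytest.approx(ols_slope, abs=1e-6)
        assert any("OLS" in note for note in res.notes)


def brute_force_partial_r(x, y, cohort):
    """Independent oracle: explicit two-step residual regression."""
    dummies = pd.get_dummies(pd.Series(cohort), dtype=float).to_numpy()
    Z = np.column_stack([np.ones(len(x)), dummies[:, 1:]])
    rx = x - Z @ np.linalg.lstsq(Z, x, rcond=None)[0]
    ry = y - Z @ np.linalg.lstsq(Z, y, rcond=None)[0]
    return float(rx @ ry / np.sqrt((rx @ rx) * (ry @ ry)))


class TestPartialCorrelation:
    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(7)
        n = 200
        cohort = np.array([f"c{k}" for k in rng.integers(0, 5, n)])
        x = rng.normal(size=n) + (cohort == "c2") * 2.0
        y = 0.4 * x + rng.normal(size=n)
        res = partial_correlation(x, y, cohort)
        assert res.r == pytest.approx(brute_force_partial_r(x, y, cohort), abs=1e-10)

    def test_single_cohort_equals_pearson(self):
        rng = np.random.default_rng(8)
        x, y = rng.normal(size=100), rng.normal(size=100)
        res = partial_correlation(x, y, np.full(100, "c0"))
        r, _ = stats.pearsonr(x, y)
        assert res.r == pytest.approx(r, abs=1e-12)

    def test_symmetric_in_arguments(self):
        rng = np.random.default_rng(9)
        cohort = np.array([f"c{k}" for k in rng.integers(0, 3, 80)])
        x, y = rng.normal(size=80), rng.normal(size=80)
        assert partial_correlation(x, y, cohort).r == partial_correlation(y, x, cohort).r

    def test_cohort_confounding_removed(self):
        # x and y share cohort means but are independent within cohort
        rng = np.random.default_rng(10)
        n, g = 400, 4
        cohort = np.repeat([f"c{k}" for k in range(g)], n // g)
        means = np.repeat(rng.normal(0, 5, g), n // g)
        x = means + rng.normal(size=n)
        y = means + rng.normal(size=n)
        raw_r, _ = stats.pearsonr(x, y)
        res = partial_correlation(x, y, cohort)
        assert abs(raw_r) > 0.5
        assert abs(res.r) < 2 / np.sqrt(n)

    def test_p_value_bounds(self):
        rng = np.random.default_rng(11)
        cohort = np.array([f"c{k}" for k in rng.integers(0, 3, 60)])
        res = partial_correlation(rng.normal(size=60), rng.normal(size=60), cohort)
        assert 0 <= res.p_value <= 1


class TestModelComparison:
    def test_duplicate_of_milke_dropped_with_zero_delta(self):
        rec = synthetic_records(n=300, seed=12)
        dup = pd.Series(rec["milke"].to_numpy(), index=rec["cow_id"])
        cmp_res = compare_rfi_models(rec, dup, "dup_trait")
        assert cmp_res.augmented_adj_r2 == pytest.approx(cmp_res.base_adj_r2, abs=1e-12)

    def test_unadjusted_r2_monotone_under_augmentation(self):
        from thermofeed import compute_rfi

        rec = synthetic_records(n=300, seed=13)
        rng = np.random.default_rng(13)
        rec["noise_trait"] = rng.normal(size=len(rec))
        base = compute_rfi(rec)
        aug = compute_rfi(rec, extra=["noise_trait"])
        assert aug.r2 >= base.r2 - 1e-12

    def test_noise_trait_barely_moves_adjusted_r2(self):
        rec = synthetic_records(n=500, seed=14)
        rng = np.random.default_rng(14)
        trait = pd.Series(rng.normal(size=len(rec)), index=rec["cow_id"])
        cmp_res = compare_rfi_models(rec, trait, "noise_trait")
        assert abs(cmp_res.augmented_adj_r2 - cmp_res.base_adj_r2) < 0.01

    def test_missing_trait_cows_dropped_from_both_fits(self):
        rec = synthetic_records(n=300, seed=15)
        trait = pd.Series(
            np.random.default_rng(15).normal(size=250), index=rec["cow_id"].iloc[:250]
        )
        cmp_res = compare_rfi_models(rec, trait, "partial_trait")
        assert cmp_res.n == 250
        assert any("250" in note for note in cmp_res.notes)
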