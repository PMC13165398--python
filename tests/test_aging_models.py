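"""Tests for behavioral clocks, lifespan forecasting, and survival stats."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import chi2

from lifespan_architect.aging_models import (
    aging_rate,
    compare_aging_rates,
    differential_usage,
    fit_behavior_clock,
    forecast_lifespan,
    survival_compare,
    trajectory_pca,
)


def monotone_cohort(n_animals=8, n_factors=5, noise=0.0, seed=0, max_age=200):
    """Factors that are a fixed monotone function of age plus optional noise."""
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_animals):
        ages = np.arange(10, max_age, 5)
        for a in ages:
            f = np.array([a / max_age, (a / max_age) ** 2, np.sqrt(a / max_age),
                          np.log1p(a) / 6, a / max_age * 0.5][:n_factors])
            f = f + rng.normal(0, noise, n_factors)
            rows.append({"animal": f"m{i}", "age": float(a),
                         **{f"tc{r}": f[r] for r in range(n_factors)}})
    return pd.DataFrame(rows)


class TestTrajectoryPCA:
    def test_identical_animals_zero_variance_at_every_age(self):
        df = monotone_cohort(noise=0.0)
        out = trajectory_pca(df, n_pcs=3)
        assert np.allclose(out["variance_by_age"]["summed_variance"], 0.0)

    def test_diverging_groups_increase_variance_with_age(self):
        rng = np.random.default_rng(0)
        rows = []
        for i in range(10):
            drift = 1.0 if i % 2 else -1.0
            for a in np.arange(10, 150, 5):
                val = drift * (a / 150) ** 2 + rng.normal(0, 0.01)
                rows.append({"animal": f"m{i}", "age": float(a), "tc0": val,
                             "tc1": rng.normal()})
        out = trajectory_pca(pd.DataFrame(rows), n_pcs=2)
        v = out["variance_by_age"].sort_values("age")["summed_variance"].to_numpy()
        assert v[-1] > v[0]

    def test_complete_pcs_reproduce_zscored_data(self):
        df = monotone_cohort(noise=0.05, n_factors=3)
        out = trajectory_pca(df, n_pcs=3)
        cols = ["tc0", "tc1", "tc2"]
        X = df[cols].to_numpy()
        Z = (X - X.mean(0)) / X.std(0)
        recon = out["trajectories"][["pc1", "pc2", "pc3"]].to_numpy() @ out["loadings"].T
        assert np.allclose(recon, Z, atol=1e-8)

    def test_too_few_rows_rejected(self):
        df = monotone_cohort().head(2)
        with pytest.raises(ValueError, match="fewer"):
            trajectory_pca(df, n_pcs=3)


class TestBehaviorClock:
    def test_noiseless_monotone_mapping_recovered(self):
        clock = fit_behavior_clock(monotone_cohort(noise=0.0), seed=0)
        assert clock.pearson_r > 0.99

    def test_no_leakage_into_training_folds(self):
        clock = fit_behavior_clock(monotone_cohort(noise=0.1), seed=0)
        for held, trained_on in clock.training_animals.items():
            assert held not in trained_on

    def test_age_independent_factors_give_no_signal(self):
        rng = np.random.default_rng(1)
        df = monotone_cohort(noise=0.0)
        for c in [c for c in df.columns if c.startswith("tc")]:
            df[c] = rng.normal(size=len(df))
        clock = fit_behavior_clock(df, seed=0)
        assert abs(clock.pearson_r) < 0.3
        # predictions concentrate near the training-age mean
        spread = clock.predictions["estimated_age"].std()
        assert spread < df["age"].std() * 0.5

    def test_importances_nonnegative_sum_to_one(self):
        clock = fit_behavior_clock(monotone_cohort(noise=0.05), seed=0)
        imp = clock.feature_importances
        assert (imp >= 0).all()
        assert np.isclose(imp.sum(), 1.0)

    def test_fewer_than_three_animals_rejected(self):
        df = monotone_cohort(n_animals=2)
        with pytest.raises(ValueError, match="3 animals"):
            fit_behavior_clock(df)


class TestAgingRate:
    def _clock_with_predictions(self, df):
        from lifespan_architect.aging_models import ClockResult

        return ClockResult(predictions=df)

    def test_perfect_estimates_slope_one(self):
        df = pd.DataFrame({"animal": "a", "age": np.arange(10.0, 100.0, 10),
                           "estimated_age": np.arange(10.0, 100.0, 10)})
        rates = aging_rate(self._clock_with_predictions(df))
        assert rates["slope"].iloc[0] == pytest.approx(1.0)

    def test_half_speed_estimates_slope_half(self):
        ages = np.arange(10.0, 100.0, 10)
        df = pd.DataFrame({"animal": "a", "age": ages,
                           "estimated_age": 0.5 * ages + 7.0})
        rates = aging_rate(self._clock_with_predictions(df))
        assert rates["slope"].iloc[0] == pytest.approx(0.5)
        assert rates["intercept"].iloc[0] == pytest.approx(7.0)

    def test_time_dilated_group_detected(self):
        # group B ages at half speed: factors follow f(age/2)
        base = monotone_cohort(n_animals=6, noise=0.02, seed=2, max_age=200)
        slow = monotone_cohort(n_animals=6, noise=0.02, seed=3, max_age=200)
        slow["animal"] = slow["animal"].str.replace("m", "s")
        # stretch ages so the same factor values appear at double the age
        slowed = slow.assign(age=slow["age"] * 2)
        df = pd.concat([base, slowed], ignore_index=True)
        clock = fit_behavior_clock(df, seed=0)
        rates = aging_rate(clock)
        groups = {a: ("slow" if a.startswith("s") else "normal")
                  for a in df["animal"].unique()}
        res = compare_aging_rates(rates, groups)
        med = dict(zip(res["groups"], res["medians"]))
        assert med["slow"] / med["normal"] == pytest.approx(0.5, abs=0.15)
        assert res["p"] < 0.05

    def test_single_day_animal_missing_slope(self):
        df = pd.DataFrame({"animal": ["a"], "age": [50.0], "estimated_age": [60.0]})
        rates = aging_rate(self._clock_with_predictions(df))
        assert np.isnan(rates["slope"].iloc[0])


class TestForecastLifespan:
    def _cohort(self, sep=5.0, seed=0, n=16):
        """Half short-lived (150 d), half long-lived (250 d); group-shifted."""
        rng = np.random.default_rng(seed)
        rows, lifespans = [], {}
        for i in range(n):
            long_lived = i % 2 == 0
            lifespans[f"f{i}"] = 250.0 if long_lived else 150.0
            shift = sep if long_lived else 0.0
            for a in np.arange(60.0, 100.0, 2.0):
                rows.append({"animal": f"f{i}", "age": a,
                             "tc0": rng.normal(shift, 1.0),
                             "tc1": rng.normal(0, 1.0)})
        return pd.DataFrame(rows), lifespans

    def test_boundary_lifespan_is_long_lived(self):
        df, lifespans = self._cohort()
        lifespans["f1"] = 200.0  # exactly at the threshold
        fc = forecast_lifespan(df, lifespans, prediction_age=90.0, seed=0)
        row = fc.predictions[fc.predictions["animal"] == "f1"]
        assert row["label"].item() == 1

    def test_disjoint_groups_perfect_auc(self):
        df, lifespans = self._cohort(sep=8.0)
        fc = forecast_lifespan(df, lifespans, prediction_age=90.0, seed=0)
        assert fc.roc_auc == 1.0
        assert fc.accuracy == 1.0

    def test_extreme_agers_excluded(self):
        df, lifespans = self._cohort()
        lifespans["f0"] = 320.0
        fc = forecast_lifespan(df, lifespans, prediction_age=90.0, seed=0)
        assert "f0" not in set(fc.predictions["animal"])

    def test_dead_before_prediction_age_excluded(self):
        df, lifespans = self._cohort()
        lifespans["f3"] = 80.0
        fc = forecast_lifespan(df, lifespans, prediction_age=90.0, seed=0)
        assert "f3" not in set(fc.predictions["animal"])

    def test_no_leakage_into_training_folds(self):
        df, lifespans = self._cohort()
        fc = forecast_lifespan(df, lifespans, prediction_age=90.0, seed=0)
        for held, trained_on in fc.training_animals.items():
            assert held not in trained_on

    def test_permuted_labels_near_chance(self):
        df, lifespans = self._cohort(sep=0.0, seed=1, n=20)
        rng = np.random.default_rng(2)
        ls = dict(zip(lifespans.keys(),
                      rng.permutation(list(lifespans.values()))))
        fc = forecast_lifespan(df, ls, prediction_age=90.0, seed=0)
        # binomial null on 20 animals: AUC within a wide chance band
        assert 0.15 < fc.roc_auc < 0.85

    def test_scaling_features_leaves_metrics_unchanged(self):
        df, lifespans = self._cohort(sep=3.0)
        fc1 = forecast_lifespan(df, lifespans, prediction_age=90.0, seed=0)
        df2 = df.copy()
        df2["tc0"] *= 100.0
        df2["tc1"] *= 0.01
        fc2 = forecast_lifespan(df2, lifespans, prediction_age=90.0, seed=0)
        assert fc1.roc_auc == pytest.approx(fc2.roc_auc, abs=1e-9)
        assert fc1.accuracy == pytest.approx(fc2.accuracy, abs=1e-9)


class TestSurvivalCompare:
    def test_km_median_equals_sample_median_without_censoring(self):
        # odd group size: the KM median (first time S <= 0.5) is the sample
        # median order statistic when nothing is censored
        lifespans = np.array([100.0, 150, 200, 250, 300, 120, 180, 240])
        groups = np.array(["a"] * 5 + ["b"] * 3)
        res = survival_compare(lifespans, groups)
        assert res["km"]["a"].median_survival_time_ == np.median(lifespans[:5])

    def test_identical_groups_statistic_zero(self):
        lifespans = np.array([50.0, 60, 70, 50, 60, 70])
        groups = np.array(["a", "a", "a", "b", "b", "b"])
        res = survival_compare(lifespans, groups)
        assert res["statistic"] == pytest.approx(0.0, abs=1e-10)
        assert res["p"] == pytest.approx(1.0)

    def test_toy_groups_match_hand_worked_tables(self):
        # groups {2,4,6} vs {8,10,12}, no censoring.  Hand computation from
        # the per-event-time risk tables: O-E = 1.85, Var = 0.6775,
        # chi2 = 1.85^2 / 0.6775 = 5.05166...
        lifespans = np.array([2.0, 4, 6, 8, 10, 12])
        groups = np.array(["a", "a", "a", "b", "b", "b"])
        res = survival_compare(lifespans, groups)
        expected_stat = 1.85**2 / 0.6775
        assert res["statistic"] == pytest.approx(expected_stat, abs=1e-6)
        assert res["p"] == pytest.approx(chi2.sf(expected_stat, 1), abs=1e-9)

    def test_all_censored_reported_undefined(self):
        lifespans = np.array([100.0, 200, 150, 250])
        groups = np.array(["a", "a", "b", "b"])
        with pytest.warns(UserWarning, match="censored"):
            res = survival_compare(lifespans, groups,
                                   censored=np.ones(4, dtype=bool))
        assert np.isnan(res["p"])


class TestDifferentialUsage:
    def _cohort(self, shift=0.0, seed=0, n=16, n_factors=4):
        rng = np.random.default_rng(seed)
        assignment = rng.permutation(np.repeat(["long", "short"], n // 2))
        rows, groups = [], {}
        for i in range(n):
            g = assignment[i]
            groups[f"f{i}"] = g
            for a in (50.0, 60.0, 70.0):
                f = rng.normal(0, 1, n_factors)
                if g == "long":
                    f[2] += shift
                rows.append({"animal": f"f{i}", "age": a,
                             **{f"tc{r}": f[r] for r in range(n_factors)}})
        return pd.DataFrame(rows), groups

    def test_identical_groups_type_one_controlled(self):
        # Bonferroni controls the family-wise rate at 0.05 within each age
        # block; over 30 blocks the chance of > 4 rejections is < 1e-3
        blocks_hit = 0
        for seed in range(10):
            df, groups = self._cohort(shift=0.0, seed=seed)
            res = differential_usage(df, groups, np.array([50.0, 60.0, 70.0]))
            blocks_hit += int(
                res.groupby("age")["significant"].any().sum()
            )
        assert blocks_hit <= 4

    def test_shifted_factor_and_only_it_detected(self):
        df, groups = self._cohort(shift=5.0, seed=1)
        res = differential_usage(df, groups, np.array([50.0, 60.0, 70.0]))
        sig = res[res["significant"]]
        assert set(sig["factor"]) == {"tc2"}
        assert len(sig) == 3  # at every tested age

    def test_bonferroni_arithmetic(self):
        # m = 45 factors, raw p = 0.002 -> adjusted p = 0.09
        assert min(1.0, 45 * 0.002) == pytest.approx(0.09)
        df, groups = self._cohort(shift=0.0, seed=2)
        res = differential_usage(df, groups, np.array([50.0]))
        m = df.filter(like="tc").shape[1]
        assert np.allclose(res["p_adj"],
                           np.minimum(1.0, m * res["p_raw"]), atol=1e-12)
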