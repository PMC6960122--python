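"""Synthetic cohort generator: determinism, configuration validation,
closed-form CA19-9 expectations, texture-drift direction, and survival
generating-model sanity."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from deltarad.simulate import (
    CohortConfig,
    ConfigError,
    generate_ca199,
    generate_cohort,
    generate_survival,
    generate_volume_series,
    simulate_lme_dataset,
    simulate_weekly_biomarkers,
    week_of_fraction,
)
from deltarad.textures import extract_features, FeatureConfig


def small_config(**kw):
    base = dict(
        n_patients=4,
        n_fractions=6,
        volume_shape=(12, 12, 12),
        roi_radius_voxels=4.5,
        ca199_schedule=(0, 3, 6),
        seed=11,
    )
    base.update(kw)
    return CohortConfig(**base)


class TestConfig:
    @pytest.mark.parametrize(
        "bad",
        [
            {"n_fractions": 1},
            {"group_split": 1.5},
            {"roi_radius_voxels": 20.0},
            {"ca199_weekly_multiplier_bad": 0.0},
            {"ca199_schedule": (3, 6)},  # no baseline
            {"ca199_schedule": (0, 1)},  # nothing in the final week
            {"survival_hr_per_unit": -1.0},
            {"censor_rate": 1.0},
        ],
    )
    def test_invalid_configs_rejected(self, bad):
        with pytest.raises(ConfigError):
            small_config(**bad).validate()

    def test_truth_round_trips_config(self):
        cfg = small_config()
        truth = generate_cohort(cfg, with_volumes=False).truth
        rebuilt = CohortConfig(
            **{
                **truth,
                "volume_shape": tuple(truth["volume_shape"]),
                "ca199_schedule": tuple(truth["ca199_schedule"]),
            }
        )
        assert rebuilt == cfg

    def test_week_mapping(self):
        assert week_of_fraction(17) == 4 and week_of_fraction(18) == 4
        assert week_of_fraction(28) == 6
        assert week_of_fraction(0) == 0


class TestVolumes:
    def test_same_seed_bit_identical(self):
        cfg = small_config()
        a = generate_volume_series("good", cfg, np.random.default_rng(5))
        b = generate_volume_series("good", cfg, np.random.default_rng(5))
        c = generate_volume_series("good", cfg, np.random.default_rng(6))
        for f in a:
            np.testing.assert_array_equal(a[f].intensities, b[f].intensities)
        assert not np.array_equal(a[1].intensities, c[1].intensities)

    def test_zero_drift_entropy_flat(self):
        cfg = small_config(
            texture_drift_good=0.0, texture_drift_sd=0.0,
            n_fractions=3, ca199_schedule=(0, 3),
        )
        series = generate_volume_series("good", cfg, np.random.default_rng(1))
        ent = [
            extract_features(series[f], FeatureConfig(n_levels=16))["entropy"]
            for f in (1, 2, 3)
        ]
        assert max(ent) - min(ent) < 0.25 * np.mean(ent)

    def test_negative_drift_entropy_slope_negative(self):
        # disorder parameter halves by the last fraction
        n = 10
        cfg = small_config(
            n_fractions=n,
            texture_drift_good=-(1 - 0.5 ** (1 / (n - 1))),
            texture_drift_sd=0.0,
            ca199_schedule=(0, 5, 10),
        )
        series = generate_volume_series("good", cfg, np.random.default_rng(2))
        ent = [
            extract_features(series[f], FeatureConfig(n_levels=16))["entropy"]
            for f in range(1, n + 1)
        ]
        slope = stats.linregress(np.arange(1, n + 1), ent).slope
        assert slope < 0

    def test_cohort_all_patients_have_fraction_one(self):
        cohort = generate_cohort(small_config())
        assert all(1 in fr for fr in cohort.volumes.values())


class TestCA199:
    def test_zero_noise_flat_multiplier(self):
        cfg = small_config(
            ca199_weekly_multiplier_good=1.0,
            ca199_noise_cv=0.0,
            ca199_trend_log_sd=0.0,
        )
        rec = generate_ca199("good", cfg, np.random.default_rng(3))
        assert rec["value"].nunique() == 1

    def test_closed_form_week_two(self):
        cfg = small_config(
            n_fractions=28,
            ca199_schedule=(0, 10, 28),
            ca199_weekly_multiplier_bad=1.2,
            ca199_noise_cv=0.0,
            ca199_trend_log_sd=0.0,
            ca199_baseline_log_sd=0.0,
            ca199_baseline_log_mean=math.log(100.0),
        )
        rec = generate_ca199("bad", cfg, np.random.default_rng(4))
        # fraction 10 -> week 2 -> 100 * 1.2^2 = 144
        v10 = float(rec.loc[rec["fraction"] == 10, "value"].iloc[0])
        assert v10 == pytest.approx(144.0)
        assert (rec["value"] > 0).all()

    def test_good_responders_mean_final_change_positive(self):
        # decline (multiplier < 1) => positive normalized change per the
        # decline-positive sign convention; Monte-Carlo mean vs closed form
        cfg = small_config(
            n_fractions=28,
            ca199_schedule=(0, 28),
            ca199_weekly_multiplier_good=0.85,
            ca199_noise_cv=0.1,
            ca199_trend_log_sd=0.0,
        )
        rng = np.random.default_rng(5)
        changes = []
        for _ in range(500):
            rec = generate_ca199("good", cfg, rng)
            base = float(rec.loc[rec["fraction"] == 0, "value"].iloc[0])
            last = float(rec.loc[rec["fraction"] == 28, "value"].iloc[0])
            changes.append((base - last) / base)
        expected = 1 - 0.85 ** 6  # noise is unit-mean
        assert np.mean(changes) == pytest.approx(expected, abs=0.02)


class TestSurvival:
    def test_no_censoring_all_events(self):
        cfg = small_config(censor_rate=0.0)
        labels = pd.DataFrame(
            {"patient_id": ["a", "b"], "group": ["good", "bad"]}
        )
        changes = pd.Series([0.5, -0.5], index=["a", "b"])
        rec = generate_survival(labels, changes, cfg, np.random.default_rng(6))
        assert (rec["event"] == 1).all()
        assert (rec["time_months"] > 0).all()

    def test_km_median_matches_exponential(self):
        # hr_per_unit = 1 -> covariate-free exponential with known median
        cfg = small_config(
            survival_hr_per_unit=1.0,
            censor_rate=0.0,
            baseline_median_survival_months=40.0,
        )
        labels = pd.DataFrame(
            {"patient_id": [f"p{i}" for i in range(1000)], "group": ["good"] * 1000}
        )
        changes = pd.Series(np.zeros(1000), index=labels["patient_id"])
        rec = generate_survival(labels, changes, cfg, np.random.default_rng(7))
        assert np.median(rec["time_months"]) == pytest.approx(40.0, rel=0.1)

    def test_censor_rate_controls_marginal_censoring(self):
        cfg = small_config(survival_hr_per_unit=1.0, censor_rate=0.4)
        labels = pd.DataFrame(
            {"patient_id": [f"p{i}" for i in range(2000)], "group": ["good"] * 2000}
        )
        changes = pd.Series(np.zeros(2000), index=labels["patient_id"])
        rec = generate_survival(labels, changes, cfg, np.random.default_rng(8))
        assert (rec["event"] == 0).mean() == pytest.approx(0.4, abs=0.04)


class TestTrajectoryGenerators:
    def test_lme_dataset_shape_and_groups(self, rng):
        df = simulate_lme_dataset(6, 5, 0.7, rng)
        assert len(df) == 12 * 5
        assert set(df["group"]) == {"good", "bad"}
        means = df.groupby("group")["value"].mean()
        assert means["good"] > means["bad"]

    def test_weekly_divergence_onsets(self, rng):
        df = simulate_weekly_biomarkers(
            200, 4, {"drf": 3, "ca199": 4}, rng, effect_sd=2.0
        )
        sep = (
            df.groupby(["biomarker", "week", "group"])["value"].mean().unstack("group")
        )
        gap = sep["good"] - sep["bad"]
        assert abs(gap.loc[("drf", 2)]) < 0.5
        assert gap.loc[("drf", 3)] == pytest.approx(2.0, abs=0.5)
        assert abs(gap.loc[("ca199", 3)]) < 0.5
        assert gap.loc[("ca199", 4)] == pytest.approx(2.0, abs=0.5)
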