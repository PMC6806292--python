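"""Virtual-patient generator: cohort sampling, scenarios, CGM, imputation,
meal-absorption classification."""

import numpy as np
import pytest
from scipy.stats import truncnorm

import glucast
from glucast import (CGMSeries, CohortConfig, classify_meal, generate_cgm,
                     generate_scenario, impute_gaps, make_ra_profile,
                     sample_cohort)
from glucast.params import SI_BOUNDS
from glucast.synthetic import RaProfile, carb_ratio_g_per_unit


class TestSampleCohort:
    def test_zero_spreads_give_identical_copies(self):
        cfg = CohortConfig(n_subjects=4, si_sd=0, gb_sd=0, w_sd=0,
                           tmaxi_frac=0, tmaxg_frac=0, ag_frac=0, seed=1)
        cohort = sample_cohort(cfg)
        ref = cohort[0].to_dict()
        assert all(p.to_dict() == ref for p in cohort)

    def test_seed_determinism(self):
        a = sample_cohort(CohortConfig(n_subjects=5, seed=9))
        b = sample_cohort(CohortConfig(n_subjects=5, seed=9))
        assert [p.to_dict() for p in a] == [p.to_dict() for p in b]

    def test_si_dispersion_matches_target_moments(self):
        """At n=1000 the sampled insulin-sensitivity moments match the
        truncated-normal target (oracle: closed-form truncnorm moments)."""
        cfg = CohortConfig(n_subjects=1000, seed=3)
        si = np.array([p.si for p in sample_cohort(cfg)])
        a = (SI_BOUNDS[0] - cfg.si_mean) / cfg.si_sd
        b = (SI_BOUNDS[1] - cfg.si_mean) / cfg.si_sd
        dist = truncnorm(a, b, loc=cfg.si_mean, scale=cfg.si_sd)
        assert si.mean() == pytest.approx(dist.mean(), rel=0.05)
        assert si.std() == pytest.approx(dist.std(), rel=0.10)
        assert si.min() >= SI_BOUNDS[0] and si.max() <= SI_BOUNDS[1]

    def test_parameters_respect_admissible_boxes(self):
        for p in sample_cohort(CohortConfig(n_subjects=50, seed=6)):
            p.validate()


class TestGenerateScenario:
    def test_zero_jitter_reproduces_daily_pattern(self, default_params):
        cfg = CohortConfig(meal_time_sd=0, meal_size_cv=0,
                           carb_err_low=0, carb_err_high=0, seed=2)
        true_sched, logged = generate_scenario(cfg, 2, default_params)
        times = [ev.time_min % 1440 for ev in true_sched.meals]
        grams = [ev.grams for ev in true_sched.meals]
        assert times == [420, 780, 1140] * 2
        assert grams == [70, 100, 80] * 2
        assert [ev.grams for ev in logged.meals] == grams

    def test_two_weeks_have_42_meals(self, default_params):
        cfg = CohortConfig(seed=5)
        true_sched, _ = generate_scenario(cfg, 14, default_params)
        assert len(true_sched.meals) == 42
        assert len(true_sched.boluses) == 42

    def test_meal_size_cv_matches_target(self, default_params):
        cfg = CohortConfig(seed=8, meal_time_sd=0)
        rng = np.random.default_rng(8)
        true_sched, _ = generate_scenario(cfg, 1000, default_params, rng)
        breakfast = np.array([ev.grams for ev in true_sched.meals[0::3]])
        assert breakfast.std() / breakfast.mean() == pytest.approx(0.10, abs=0.02)

    def test_carb_error_support(self, default_params):
        cfg = CohortConfig(seed=8)
        rng = np.random.default_rng(9)
        true_sched, logged = generate_scenario(cfg, 400, default_params, rng)
        ratio = np.array([l.grams / t.grams
                          for t, l in zip(true_sched.meals, logged.meals)])
        assert ratio.min() >= 0.70 - 1e-12
        assert ratio.max() <= 1.20 + 1e-12
        # both tails of the uniform support are reached
        assert ratio.min() < 0.72 and ratio.max() > 1.18

    def test_bolus_rule_follows_logged_carbs(self, default_params):
        cfg = CohortConfig(seed=4)
        rng = np.random.default_rng(4)
        _, logged = generate_scenario(cfg, 3, default_params, rng)
        ratio = carb_ratio_g_per_unit(default_params, cfg.bolus_target_glucose)
        for meal, bolus in zip(logged.meals, logged.boluses):
            assert bolus.units == pytest.approx(meal.grams / ratio, abs=0.01)


class TestGenerateCgm:
    def test_noiseless_subsampling_is_exact(self, default_params):
        cfg = CohortConfig(cgm_sigma=0, gap_rate_per_day=0, seed=1)
        truth = np.linspace(100, 200, 1441)
        cgm = generate_cgm(truth, cfg)
        np.testing.assert_array_equal(cgm.g, truth[::5])
        assert cgm.is_regular

    def test_noise_std_matches_sigma(self):
        cfg = CohortConfig(cgm_sigma=10.0, cgm_ar1=0.7, gap_rate_per_day=0, seed=2)
        truth = np.full(14 * 1440 + 1, 150.0)
        cgm = generate_cgm(truth, cfg)
        assert np.std(cgm.g - 150.0) == pytest.approx(10.0, rel=0.15)

    def test_ar1_noise_is_autocorrelated(self):
        cfg = CohortConfig(cgm_sigma=10.0, cgm_ar1=0.7, gap_rate_per_day=0, seed=2)
        truth = np.full(14 * 1440 + 1, 150.0)
        e = generate_cgm(truth, cfg).g - 150.0
        r1 = np.corrcoef(e[:-1], e[1:])[0, 1]
        assert r1 == pytest.approx(0.7, abs=0.1)

    def test_gap_windows_are_removed(self):
        cfg = CohortConfig(cgm_sigma=0, gap_rate_per_day=2.0,
                           gap_dur_min=30, gap_dur_max=30, seed=12)
        truth = np.full(2 * 1440 + 1, 120.0)
        cgm = generate_cgm(truth, cfg)
        n_grid = len(np.arange(0, truth.size, 5))
        assert len(cgm) < n_grid
        assert np.all(np.diff(cgm.t) % 5 == 0)


class TestImputeGaps:
    def test_gapless_series_is_identity(self):
        cgm = CGMSeries(np.arange(10) * 5.0, np.linspace(100, 150, 10))
        out = impute_gaps(cgm)
        np.testing.assert_array_equal(out.g, cgm.g)
        assert not out.imputed.any()

    def test_linear_segment_recovered_exactly(self):
        t_all = np.arange(20) * 5.0
        g_all = 100.0 + 2.0 * t_all / 5.0
        keep = np.ones(20, dtype=bool)
        keep[8:12] = False
        out = impute_gaps(CGMSeries(t_all[keep], g_all[keep]))
        assert len(out) == 20
        np.testing.assert_allclose(out.g, g_all, rtol=1e-12)
        assert out.imputed.sum() == 4

    def test_beats_linear_interpolation_on_curvature(self):
        t_all = np.arange(60) * 5.0
        g_all = 150.0 + 40.0 * np.sin(t_all * 2 * np.pi / 180.0)
        keep = np.ones(60, dtype=bool)
        keep[30:33] = False
        cgm = CGMSeries(t_all[keep], g_all[keep])
        out = impute_gaps(cgm)
        missing = t_all[~keep]
        akima_err = np.max(np.abs(out.g[~keep] - g_all[~keep]))
        linear = np.interp(missing, t_all[keep], g_all[keep])
        linear_err = np.max(np.abs(linear - g_all[~keep]))
        assert akima_err < linear_err

    def test_flags_preserved_and_set(self):
        t = np.array([0.0, 5.0, 15.0])
        cgm = CGMSeries(t, np.array([100.0, 110.0, 120.0]))
        out = impute_gaps(cgm)
        np.testing.assert_array_equal(out.imputed, [False, False, True, False])


class TestMealClassification:
    def test_immediate_impulse_is_fast(self):
        t = np.arange(0, 300.0)
        ra = np.zeros(t.size)
        ra[:10] = 100.0
        assert classify_meal(RaProfile(t=t, ra=ra, grams=10)) == "fast"

    def test_uniform_six_hour_profile_is_slow(self):
        # 2-h share = 1/3 <= 0.6 and 4-h share = 2/3 < 0.8
        t = np.arange(0, 361.0)
        assert classify_meal(RaProfile(t=t, ra=np.full(t.size, 50.0), grams=60)) == "slow"

    def test_middle_band_is_medium(self):
        # 50% of area in first 2 h, remaining 50% in hours 2-3:
        # 2-h share 0.5 <= 0.6, 4-h share 1.0 >= 0.8
        t = np.arange(0, 181.0)
        ra = np.where(t < 120, 50.0, 100.0)
        assert classify_meal(RaProfile(t=t, ra=ra, grams=30)) == "medium"

    def test_zero_area_rejected(self):
        with pytest.raises(ValueError):
            classify_meal(RaProfile(t=np.arange(10.0), ra=np.zeros(10), grams=1))

    def test_profile_auc_equals_bioavailable_dose(self, default_params):
        prof = make_ra_profile("medium", 60.0, default_params)
        auc = np.trapezoid(prof.ra, prof.t)
        assert auc == pytest.approx(0.85 * 60000.0, rel=0.005)

    def test_class_round_trip_at_default_kinetics(self, default_params):
        for cls in ("fast", "medium", "slow"):
            prof = make_ra_profile(cls, 60.0, default_params)
            assert classify_meal(prof) == cls

    def test_peak_times_ordered_by_class(self, default_params):
        peaks = {cls: make_ra_profile(cls, 60.0, default_params).t[
            np.argmax(make_ra_profile(cls, 60.0, default_params).ra)]
            for cls in ("fast", "medium", "slow")}
        assert peaks["fast"] < peaks["medium"] < peaks["slow"]


class TestEndToEnd:
    def test_full_dataset_determinism(self):
        cfg = CohortConfig(n_subjects=1, seed=33)

        def build():
            p = sample_cohort(cfg)[0]
            rng = np.random.default_rng(34)
            return glucast.generate_subject_dataset(p, cfg, 2, rng)

        a, b = build(), build()
        np.testing.assert_array_equal(a.truth, b.truth)
        np.testing.assert_array_equal(a.cgm.g, b.cgm.g)
        assert [ev.grams for ev in a.logged_schedule.meals] == \
            [ev.grams for ev in b.logged_schedule.meals]
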