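"""Generator contracts: determinism, degenerate configs, profiles, artifacts."""

import numpy as np
import pandas as pd
import pytest

from workhrr import hrr, ibi_qc
from workhrr.coda_stats import ilr_inverse, ilr_two_part
from workhrr.synth import (
    ArtifactConfig,
    ConfigError,
    CovariateEffects,
    ScenarioConfig,
    beat_level_ground_truth,
    build_day_profile,
    derive_ilr_slope,
    emit_beats,
    inject_artifacts,
    make_day_plan,
    simulate_cohort,
    simulate_ibi_stream,
    simulate_outcomes_metric_level,
    solve_work_profile,
)
from workhrr.synth.beats import DayPlan

from conftest import make_series


class TestCohort:
    def test_deterministic_given_seed(self):
        cfg = ScenarioConfig(seed=42, n_workers=120)
        a = simulate_cohort(cfg)
        b = simulate_cohort(cfg)
        assert a.to_csv(index=False) == b.to_csv(index=False)

    def test_different_seeds_differ(self):
        a = simulate_cohort(ScenarioConfig(seed=1, n_workers=50))
        b = simulate_cohort(ScenarioConfig(seed=2, n_workers=50))
        assert not a["vo2max_rel"].equals(b["vo2max_rel"])

    def test_degenerate_sds_hit_means(self):
        cfg = ScenarioConfig(
            seed=0, n_workers=1, age_sd=0.0, vo2_sd=0.0, mass_sd=0.0, steps_log_sd=0.0
        )
        w = simulate_cohort(cfg).iloc[0]
        assert w["age"] == 44
        assert w["vo2max_rel"] == pytest.approx(32.0)
        assert w["body_mass"] == pytest.approx(80.0)
        assert w["steps_per_hour"] == pytest.approx(np.exp(cfg.steps_log_mean))

    @pytest.mark.parametrize(
        "kw",
        [
            {"n_workers": 0},
            {"age_sd": -1.0},
            {"occupation_probs": (0.5, 0.5, 0.5, 0.5)},
            {"fidelity": "telepathy"},
            {"prop_above_median": 1.2},
        ],
    )
    def test_invalid_config_rejected(self, kw):
        with pytest.raises(ConfigError):
            ScenarioConfig(**kw).validate()

    def test_fitness_declines_with_age(self, cohort):
        r = np.corrcoef(cohort["age"], cohort["vo2max_rel"])[0, 1]
        assert -0.45 < r < -0.15

    def test_worker_invariants(self, cohort):
        assert cohort["age"].between(18, 68).all()
        assert (cohort["vo2max_rel"] > 0).all()
        assert (cohort["steps_per_hour"] >= 0).all()
        assert cohort["n_days"].isin([1, 2, 3, 4]).all()


class TestMetricOutcomes:
    def test_deterministic(self, default_cfg, cohort):
        a, ta = simulate_outcomes_metric_level(cohort, default_cfg)
        b, tb = simulate_outcomes_metric_level(cohort, default_cfg)
        assert a.to_csv(index=False) == b.to_csv(index=False)
        assert ta.to_csv(index=False) == tb.to_csv(index=False)

    def test_null_effect_zero_noise_is_constant(self):
        cfg = ScenarioConfig(
            seed=3,
            n_workers=40,
            beta_mean=0.0,
            covariate_effects=CovariateEffects(female=0.0, occupation=(0,) * 4, shift=(0,) * 3),
            hrr_mean_sd=0.0,
        )
        s, _ = simulate_outcomes_metric_level(simulate_cohort(cfg), cfg)
        assert s["hrr_mean"].nunique() == 1
        assert s["hrr_mean"].iloc[0] == pytest.approx(30.0)

    def test_ilr_slope_matches_finite_difference(self):
        # the derived ilr slope must reproduce the configured absolute change
        # when pushed through the inverse-ilr curve at the compositional median
        p_ref, delta = 0.47, -1.8
        b_z = derive_ilr_slope(delta, p_ref)
        z_ref = ilr_two_part(p_ref)
        assert 100.0 * (ilr_inverse(z_ref + b_z) - p_ref) == pytest.approx(delta, abs=1e-10)
        # first-order consistency with the derivative of p(z)
        h = 1e-6
        dp_dz = (ilr_inverse(z_ref + h) - ilr_inverse(z_ref - h)) / (2 * h)
        assert b_z == pytest.approx((delta / 100.0) / dp_dz, rel=0.02)

    def test_ground_truth_matches_summaries_minus_noise(self, default_cfg, cohort):
        s, t = simulate_outcomes_metric_level(cohort, default_cfg)
        resid = s["hrr_mean"].to_numpy() - t["true_hrr_mean"].to_numpy()
        assert abs(resid.mean()) < 1.0  # residuals centred
        assert resid.std() > 1.0  # and genuinely noisy


class TestBeatStreams:
    def test_constant_hour_of_beats(self):
        t, ibi = emit_beats([(0.0, 3600.0, 60.0)])
        assert len(t) == 3600
        assert np.allclose(ibi, 1000.0)

    def test_sleep_trough_recovered_downstream(self):
        plan = make_day_plan(ScenarioConfig())
        profile = build_day_profile(plan, 55.0, 177.2, 30.0, 57.0, 0.47, 12.0)
        t, ibi = emit_beats(profile)
        s = make_series(ibi, start_s=0.0)
        cleaned, _ = ibi_qc.clean_series(s)
        assert hrr.hr_min_10beat(cleaned.hr_bpm) == pytest.approx(55.0, abs=0.01)

    def test_work_mean_hr_matches_arithmetic(self):
        hr_min, age, g_mean = 60.0, 44, 30.0
        hr_max = hrr.hr_max_tanaka(age)  # 208 - 0.7*44
        plan = make_day_plan(ScenarioConfig())
        profile = build_day_profile(plan, hr_min, hr_max, g_mean, 57.0, 0.47, 12.0)
        t, ibi = emit_beats(profile)
        work = (t > plan.work[0]) & (t <= plan.work[1])
        hr = 60000.0 / ibi
        expected = hr_min + g_mean / 100.0 * (hr_max - hr_min)
        # time-weighted mean work HR (each beat spans its own interval)
        got = np.average(hr[work], weights=ibi[work])
        assert got == pytest.approx(expected, abs=0.2)

    def test_profile_solver_hits_targets(self, rng):
        work_s = 7.5 * 3600.0
        for _ in range(50):
            g_max = rng.uniform(40.0, 90.0)
            g_prop = rng.uniform(0.05, 0.9)
            segs = None
            while segs is None:
                g_mean = rng.uniform(10.0, 60.0)
                segs = solve_work_profile(g_mean, g_max, g_prop, work_s)
            durs = np.array([d for d, _ in segs])
            lvls = np.array([v for _, v in segs])
            assert durs.sum() == pytest.approx(work_s)
            assert np.average(lvls, weights=durs) == pytest.approx(g_mean, abs=1e-6)
            assert durs[(lvls >= 30.0)].sum() == pytest.approx(g_prop * work_s, abs=1e-6)
            assert lvls.max() == pytest.approx(g_max)

    def test_overlapping_day_plan_rejected(self):
        plan = DayPlan(sleep=(0.0, 8 * 3600.0), work=(7 * 3600.0, 15 * 3600.0), leisure=())
        with pytest.raises(ConfigError, match="overlap"):
            plan.validate()

    def test_diary_consistent_with_streams(self, default_cfg):
        cfg = default_cfg.replace(n_workers=2, fidelity="beat_level")
        w = simulate_cohort(cfg)
        s, _ = simulate_outcomes_metric_level(w, cfg)
        truth = beat_level_ground_truth(w, s, cfg)
        series, diary = simulate_ibi_stream(w.iloc[0], truth.iloc[0], cfg)
        assert len(series) == w.iloc[0]["n_days"]
        days = {iv.day for iv in diary}
        assert days == {x.day for x in series}


class TestArtifacts:
    def _clean_stream(self, n=4000):
        return make_series([800.0] * n)

    def test_zero_rates_identity(self):
        s = self._clean_stream()
        out, log = inject_artifacts(s, ArtifactConfig())
        assert np.array_equal(out.ibi_ms, s.ibi_ms)
        assert len(log) == 0

    def test_injection_log_counts(self, rng):
        s = self._clean_stream()
        out, log = inject_artifacts(
            s, ArtifactConfig(out_of_range_rate=0.01, ectopic_rate=0.02), rng=rng
        )
        assert len(log[log.kind == "out_of_range"]) == pytest.approx(40, abs=3)
        assert len(log[log.kind == "ectopic"]) == pytest.approx(80, abs=5)

    def test_qc_recall_on_injected_beats(self, rng):
        s = self._clean_stream()
        out, log = inject_artifacts(
            s, ArtifactConfig(out_of_range_rate=0.01, ectopic_rate=0.02), rng=rng
        )
        cleaned, _ = ibi_qc.clean_series(out)
        kept = set(cleaned.time_s)
        oor_times = log[log.kind == "out_of_range"]["time_s"]
        ect_times = log[log.kind == "ectopic"]["time_s"]
        assert all(t not in kept for t in oor_times)  # recall 1.0 on range rule
        ect_recall = np.mean([t not in kept for t in ect_times])
        assert ect_recall >= 0.95

    def test_nonwear_gap_removes_beats(self, rng):
        s = self._clean_stream()
        out, log = inject_artifacts(
            s, ArtifactConfig(n_nonwear_gaps=1, nonwear_gap_s=120.0), rng=rng
        )
        assert len(out) < len(s)
        assert (log.kind == "nonwear_gap").sum() == 1

    def test_invalid_rate_rejected(self):
        with pytest.raises(ConfigError):
            inject_artifacts(self._clean_stream(100), ArtifactConfig(ectopic_rate=1.5))
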