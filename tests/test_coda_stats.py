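"""Compositional transform, regression models, interaction and stratification."""

import numpy as np
import pandas as pd
import pytest

from workhrr import coda_stats
from workhrr.synth import (
    CovariateEffects,
    ScenarioConfig,
    simulate_cohort,
    simulate_outcomes_metric_level,
)


def analysis_table(cfg):
    w = simulate_cohort(cfg)
    s, _ = simulate_outcomes_metric_level(w, cfg)
    return coda_stats.build_analysis_table(w, s)


class TestIlr:
    def test_symmetry_point(self):
        assert coda_stats.ilr_two_part(0.5) == 0.0

    @pytest.mark.parametrize("p", [0.1, 0.47, 0.9])
    def test_round_trip(self, p):
        assert coda_stats.ilr_inverse(coda_stats.ilr_two_part(p)) == pytest.approx(p, abs=1e-12)

    def test_antisymmetry(self):
        for p in (0.05, 0.3, 0.47):
            assert coda_stats.ilr_two_part(p) == pytest.approx(
                -coda_stats.ilr_two_part(1.0 - p), abs=1e-12
            )

    def test_domain_error(self):
        with pytest.raises(ValueError):
            coda_stats.ilr_two_part(0.0)
        with pytest.raises(ValueError):
            coda_stats.ilr_two_part(1.0)


class TestZeroReplace:
    def test_zero_part_replaced_one_sample(self):
        total = 1000.0
        pa, pb = coda_stats.zero_replace(0.0, total, total)
        assert pa == pytest.approx(0.25 / total)
        assert pa + pb == pytest.approx(1.0, abs=1e-15)

    def test_noop_when_both_positive(self):
        pa, pb = coda_stats.zero_replace(400.0, 600.0, 1000.0)
        assert (pa, pb) == (0.4, 0.6)

    def test_closure_exact(self):
        pa, pb = coda_stats.zero_replace(1000.0, 0.0, 1000.0)
        assert pa + pb == 1.0


class TestFitModel:
    def test_zero_noise_recovers_slope_exactly(self):
        cfg = ScenarioConfig(
            seed=5,
            n_workers=80,
            covariate_effects=CovariateEffects(female=0.0, occupation=(0,) * 4, shift=(0,) * 3),
            hrr_mean_sd=0.32 * 8.9,  # all outcome variance carried by fitness
        )
        df = analysis_table(cfg)
        est = coda_stats.fit_model(df, "hrr_mean")
        assert est.slope == pytest.approx(-0.32, abs=1e-6)
        assert est.ci_low <= est.slope <= est.ci_high

    def test_rescaling_fitness_rescales_slope(self, default_cfg):
        df = analysis_table(default_cfg)
        est1 = coda_stats.fit_model(df, "hrr_mean")
        df2 = df.copy()
        df2["vo2max_rel"] = df2["vo2max_rel"] * 2.0
        est2 = coda_stats.fit_model(df2, "hrr_mean")
        assert est2.slope == pytest.approx(est1.slope / 2.0, rel=1e-9)

    def test_permuted_outcome_centred_on_zero(self):
        slopes = []
        for seed in range(8):
            df = analysis_table(ScenarioConfig(seed=seed, n_workers=300))
            rng = np.random.default_rng(seed)
            df = df.assign(hrr_mean=rng.permutation(df["hrr_mean"].to_numpy()))
            slopes.append(coda_stats.fit_model(df, "hrr_mean").slope)
        slopes = np.array(slopes)
        assert abs(slopes.mean()) < 2.5 * slopes.std(ddof=1) / np.sqrt(len(slopes))

    def test_adjusted_equals_unadjusted_without_covariate_effects(self):
        cfg = ScenarioConfig(
            seed=9,
            n_workers=400,
            covariate_effects=CovariateEffects(female=0.0, occupation=(0,) * 4, shift=(0,) * 3),
        )
        df = analysis_table(cfg)
        una = coda_stats.fit_model(df, "hrr_mean", adjusted=False)
        adj = coda_stats.fit_model(df, "hrr_mean", adjusted=True)
        assert adj.slope == pytest.approx(una.slope, abs=0.03)

    def test_too_few_rows_rejected(self, default_cfg):
        df = analysis_table(default_cfg).head(10)
        with pytest.raises(ValueError, match="complete rows"):
            coda_stats.fit_model(df, "hrr_mean")

    def test_degenerate_factor_dropped_not_fatal(self, default_cfg):
        df = analysis_table(default_cfg)
        df = df[df["sex"] == "female"]
        est = coda_stats.fit_model(df, "hrr_mean", adjusted=True)
        assert np.isfinite(est.slope)


class TestInteraction:
    def test_linear_interaction_detected_majority(self):
        # power check under an injected linear age modifier of the fitness slope
        rejections = 0
        reps = 25
        for seed in range(reps):
            cfg = ScenarioConfig(seed=seed, n_workers=497).with_linear_age_interaction()
            df = analysis_table(cfg)
            est = coda_stats.interaction_test(df, "hrr_mean")
            rejections += est.p_value < 0.05
        assert rejections > reps / 2

    def test_null_interaction_rarely_significant(self):
        pvals = []
        for seed in range(12):
            df = analysis_table(ScenarioConfig(seed=100 + seed, n_workers=300))
            pvals.append(coda_stats.interaction_test(df, "hrr_mean").p_value)
        assert np.mean(np.array(pvals) < 0.05) < 0.35

    def test_product_term_sign_matches_injection(self):
        cfg = ScenarioConfig(seed=3, n_workers=497).with_linear_age_interaction(-0.01)
        est = coda_stats.interaction_test(analysis_table(cfg), "hrr_mean")
        assert est.slope < 0


class TestStratify:
    def test_counts_partition_sample(self, default_cfg):
        df = analysis_table(default_cfg)
        for by in ("age_quartiles", "occupation", "steps_quartiles"):
            ests = coda_stats.stratify(df, by, "hrr_mean")
            assert sum(e.n for e in ests) == len(df)

    def test_pinned_age_bands_labels(self, default_cfg):
        df = analysis_table(default_cfg)
        ests = coda_stats.stratify(df, "age_quartiles", "hrr_mean", pinned=True)
        assert {e.stratum for e in ests} == {"<=37", "38-45", "46-51", ">=52"}

    def test_homogeneous_effect_consistent_across_ages(self):
        # no injected interaction: age-stratum CIs should overlap heavily
        df = analysis_table(ScenarioConfig(seed=17, n_workers=497))
        ests = coda_stats.stratify(df, "age_quartiles", "hrr_mean", pinned=True)
        lo = max(e.ci_low for e in ests)
        hi = min(e.ci_high for e in ests)
        assert lo < hi  # a common slope value lies inside every stratum CI

    def test_small_stratum_flagged_unstable(self, default_cfg):
        df = analysis_table(default_cfg).head(60)
        ests = coda_stats.stratify(df, "occupation", "hrr_mean", n_min=20)
        assert any(not e.stable for e in ests)


class TestBacktransform:
    def test_zero_slope_zero_delta(self):
        rng = np.random.default_rng(0)
        n = 200
        df = pd.DataFrame(
            {
                "vo2max_rel": rng.normal(32, 8, n),
                "ilr_z": np.full(n, coda_stats.ilr_two_part(0.47)),
            }
        )
        eff = coda_stats.backtransform_delta_pct(df)
        assert eff.delta_pct == pytest.approx(0.0, abs=1e-9)

    def test_first_order_matches_finite_difference(self, default_cfg):
        df = analysis_table(default_cfg)
        eff = coda_stats.backtransform_delta_pct(df)
        z_bar = df["ilr_z"].mean()
        h = 1e-6
        dp_dz = (coda_stats.ilr_inverse(z_bar + h) - coda_stats.ilr_inverse(z_bar - h)) / (2 * h)
        linearised = 100.0 * dp_dz * eff.ilr.slope
        assert eff.delta_pct == pytest.approx(linearised, rel=0.05)

    def test_ci_maps_through_same_curve(self, default_cfg):
        df = analysis_table(default_cfg)
        eff = coda_stats.backtransform_delta_pct(df)
        assert eff.delta_ci_low <= eff.delta_pct <= eff.delta_ci_high
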