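"""Scenario configuration for the synthetic cohort generator.

The defaults describe a mid-sized Danish blue-collar cohort wearing a chest
heart-rate monitor over consecutive 24-h days: age 44 +/- 9.8 years (range
18-68), 41% women, cardiorespiratory fitness 32 +/- 8.9 mlO2/min/kg declining
with age, an occupation mix dominated by manufacturing, and per-worker
workload outcomes centred on a mean relative heart-rate load (%HRR) of 30
with a 1-min peak of 57 and a median 47% of work time spent at or above the
30 %HRR cut-off.  Effect parameters inject a linear fitness -> workload
association (-0.32 %HRR-points of mean load and -0.35 points of peak load
per mlO2/min/kg, and -1.8 percentage points of high-load work time via the
ilr scale).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

SEXES = ("female", "male")
OCCUPATIONS = ("administration", "cleaning", "manufacturing", "transportation")
SHIFTS = ("fixed_day", "night_varying", "other")
OUTCOMES = ("hrr_mean", "hrr_max_1min", "ilr_z")

#: Age-band-specific fitness slopes for the mean-%HRR outcome used by the
#: u-shaped age-interaction scenario (strongest effect in the 46-51 band).
DEFAULT_AGE_BAND_SLOPES = {
    "hrr_mean": (-0.29, -0.37, -0.45, -0.28),
    "hrr_max_1min": (-0.39, -0.45, -0.45, -0.42),
    # composition slopes given as target percentage-point changes of work time
    "delta_pct": (-1.5, -1.9, -2.6, -1.7),
}

#: Upper edges of the pinned age bands (years): <=37, 38-45, 46-51, >=52.
DEFAULT_AGE_BAND_EDGES = (37, 45, 51)


class ConfigError(ValueError):
    """Raised when a scenario configuration is internally inconsistent."""


@dataclass
class CovariateEffects:
    """Additive covariate offsets on each outcome scale.

    Offsets are deliberately small (at most ~2 %HRR points) so that adjusted
    and unadjusted models differ measurably without dominating the outcome
    variance.  Covariates are generated independently of fitness, so the
    unadjusted fitness slope stays unbiased for the injected value.
    """

    female: float = 1.5
    occupation: tuple[float, float, float, float] = (-1.5, 1.0, 0.5, 0.0)
    shift: tuple[float, float, float] = (0.0, 1.0, 0.0)

    def scaled(self, s: float) -> "CovariateEffects":
        return CovariateEffects(
            female=self.female * s,
            occupation=tuple(v * s for v in self.occupation),
            shift=tuple(v * s for v in self.shift),
        )


@dataclass
class ArtifactConfig:
    """Rates of injected measurement artifacts on a beat stream."""

    out_of_range_rate: float = 0.0
    ectopic_rate: float = 0.0
    error_flag_rate: float = 0.0
    error_run_beats: int = 80
    n_nonwear_gaps: int = 0
    nonwear_gap_s: float = 600.0

    def validate(self) -> None:
        for name in ("out_of_range_rate", "ectopic_rate", "error_flag_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {v}")
        if self.n_nonwear_gaps < 0 or self.nonwear_gap_s <= 0:
            raise ConfigError("non-wear gap settings must be non-negative / positive")


@dataclass
class ScenarioConfig:
    """Everything the generator needs: demographics, effects, noise, structure."""

    n_workers: int = 497
    seed: int = 0
    fidelity: str = "metric_level"  # or "beat_level"

    # demographics
    age_mean: float = 44.0
    age_sd: float = 9.8
    age_bounds: tuple[float, float] = (18.0, 68.0)
    p_female: float = 0.41
    occupation_probs: tuple[float, float, float, float] = (0.153, 0.094, 0.670, 0.083)
    shift_probs: tuple[float, float, float] = (0.797, 0.143, 0.060)
    # self-rated health coded 1 = very good ... 5 = very poor
    health_probs: tuple[float, ...] = (0.086, 0.618, 0.281, 0.014, 0.001)
    p_medication: float = 0.25
    steps_log_mean: float = 7.06
    steps_log_sd: float = 0.42
    vo2_mean: float = 32.0
    vo2_sd: float = 8.9
    vo2_bounds: tuple[float, float] = (10.0, 70.0)
    mass_mean: float = 80.0
    mass_sd: float = 14.0
    mass_bounds: tuple[float, float] = (45.0, 140.0)
    age_fitness_corr: float = -0.3
    days_probs: tuple[float, float, float, float] = (0.10, 0.30, 0.45, 0.15)

    # outcome calibration targets (cohort level)
    hrr_mean_target: float = 30.0
    hrr_mean_sd: float = 7.4
    hrr_max_target: float = 57.0
    hrr_max_sd: float = 10.5
    prop_above_median: float = 0.47
    ilr_sd: float = 1.077

    # injected effects: %HRR points per mlO2/min/kg; composition as a target
    # percentage-point change of work time per unit fitness (mapped to the
    # ilr scale by inverting the back-transform at the compositional median)
    beta_mean: float = -0.32
    beta_max: float = -0.35
    delta_pct: float = -1.8

    # age-interaction profile: None, {"bands": {...}, "edges": (...)} for
    # band-specific slopes, or {"gamma": {...}} for a linear modifier on the
    # centred age x fitness product
    age_interaction: Optional[dict] = None

    covariate_effects: CovariateEffects = field(default_factory=CovariateEffects)
    covariate_ilr_scale: float = 0.06  # offsets on the ilr scale = offsets * this
    resid_corr: tuple = ((1.0, 0.5, 0.6), (0.5, 1.0, 0.4), (0.6, 0.4, 1.0))

    # beat-level structure
    work_hours: float = 7.5
    sleep_hours: float = 8.0
    work_start_h: float = 9.0
    hr_min_mean: float = 59.0
    hr_min_sd: float = 6.0
    hr_min_bounds: tuple[float, float] = (45.0, 80.0)
    leisure_hrr_pct: float = 12.0
    beat_jitter_sd: float = 0.0
    bout_s: float = 120.0

    def validate(self) -> None:
        if self.n_workers <= 0:
            raise ConfigError("n_workers must be positive")
        if self.fidelity not in ("metric_level", "beat_level"):
            raise ConfigError(f"unknown fidelity {self.fidelity!r}")
        for name in ("age_sd", "vo2_sd", "mass_sd", "hrr_mean_sd", "hrr_max_sd", "ilr_sd"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        for name, probs in (
            ("occupation_probs", self.occupation_probs),
            ("shift_probs", self.shift_probs),
            ("health_probs", self.health_probs),
            ("days_probs", self.days_probs),
        ):
            p = np.asarray(probs, dtype=float)
            if np.any(p < 0) or not math.isclose(p.sum(), 1.0, abs_tol=5e-3):
                raise ConfigError(f"{name} must be non-negative and sum to 1")
        if not 0.0 <= self.p_female <= 1.0 or not 0.0 <= self.p_medication <= 1.0:
            raise ConfigError("proportions must lie in [0, 1]")
        if not -1.0 < self.age_fitness_corr < 1.0:
            raise ConfigError("age_fitness_corr must lie in (-1, 1)")
        if not 0.0 < self.prop_above_median < 1.0:
            raise ConfigError("prop_above_median must lie in (0, 1)")
        if self.work_hours <= 0 or self.sleep_hours <= 0:
            raise ConfigError("day structure durations must be positive")
        if self.work_start_h < self.sleep_hours:
            raise ConfigError("work must start after the sleep block")
        if self.work_start_h + self.work_hours > 24.0:
            raise ConfigError("work block must end within the day")

    def replace(self, **kw) -> "ScenarioConfig":
        return replace(self, **kw)

    def with_age_interaction_bands(
        self,
        band_slopes: Optional[dict] = None,
        edges: tuple[int, ...] = DEFAULT_AGE_BAND_EDGES,
    ) -> "ScenarioConfig":
        """Scenario where the fitness slope is specific to pinned age bands."""
        bands = dict(DEFAULT_AGE_BAND_SLOPES if band_slopes is None else band_slopes)
        return self.replace(age_interaction={"bands": bands, "edges": tuple(edges)})

    def with_linear_age_interaction(self, gamma_mean: float = -0.010) -> "ScenarioConfig":
        """Scenario with a linear age modifier of the mean-%HRR fitness slope.

        ``gamma_mean`` is %HRR per (year x mlO2/min/kg) applied to the centred
        age x fitness product; the default is sized so a cohort of ~500
        detects the product term with high power.
        """
        return self.replace(age_interaction={"gamma": {"hrr_mean": gamma_mean}})


def stage_rng(config: ScenarioConfig, stage: str) -> np.random.Generator:
    """Deterministic per-stage generator derived from the scenario seed.

    Each stage (cohort, outcomes, beats, artifacts) gets an independent
    stream so that, e.g., regenerating beat streams does not perturb the
    cohort draw.
    """
    stage_ids = {"cohort": 1, "outcomes": 2, "beats": 3, "artifacts": 4, "fitness": 5}
    if stage not in stage_ids:
        raise KeyError(f"unknown rng stage {stage!r}")
    return np.random.default_rng(np.random.SeedSequence((int(config.seed), stage_ids[stage])))
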