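"""Synthetic worker cohorts: demographics and cardiorespiratory fitness."""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .config import OCCUPATIONS, SEXES, SHIFTS, ConfigError, ScenarioConfig, stage_rng

WORKER_COLUMNS = [
    "worker_id",
    "age",
    "sex",
    "occupation",
    "shift",
    "self_rated_health",
    "medication",
    "steps_per_hour",
    "vo2max_rel",
    "body_mass",
    "n_days",
]


def _matched_truncnorm_params(
    mean: float, sd: float, bounds: tuple[float, float]
) -> tuple[float, float]:
    """Pre-truncation (loc, scale) whose truncated moments equal (mean, sd).

    Configured means and SDs describe the generated sample, not a latent
    parent distribution, so truncation must not shrink them; falls back to
    the naive parameters if the moment equations cannot be solved for the
    given range.
    """
    if sd == 0:
        return mean, 0.0

    def eqs(p):
        loc, log_scale = p
        scale = float(np.exp(log_scale))
        a, b = (bounds[0] - loc) / scale, (bounds[1] - loc) / scale
        m, v = stats.truncnorm.stats(a, b, loc=loc, scale=scale, moments="mv")
        return (float(m) - mean, float(np.sqrt(v)) - sd)

    sol, _, ier, _ = optimize.fsolve(eqs, [mean, np.log(sd)], full_output=True)
    if ier != 1:
        return mean, sd
    return float(sol[0]), float(np.exp(sol[1]))


def _draw_truncated(
    rng: np.random.Generator, n: int, mean: float, sd: float, bounds: tuple[float, float]
) -> np.ndarray:
    if sd == 0:
        if not bounds[0] <= mean <= bounds[1]:
            raise ConfigError("degenerate distribution outside its truncation bounds")
        return np.full(n, mean)
    loc, scale = _matched_truncnorm_params(mean, sd, bounds)
    a, b = (bounds[0] - loc) / scale, (bounds[1] - loc) / scale
    u = rng.uniform(stats.norm.cdf(a), stats.norm.cdf(b), size=n)
    return loc + scale * stats.norm.ppf(u)


def _draw_age_fitness(rng: np.random.Generator, cfg: ScenarioConfig, n: int):
    """Jointly truncated bivariate draw of (age, fitness) with negative correlation."""
    if cfg.age_sd == 0 or cfg.vo2_sd == 0:
        age = _draw_truncated(rng, n, cfg.age_mean, cfg.age_sd, cfg.age_bounds)
        vo2 = _draw_truncated(rng, n, cfg.vo2_mean, cfg.vo2_sd, cfg.vo2_bounds)
        return age, vo2
    rho = cfg.age_fitness_corr
    loc_a, scale_a = _matched_truncnorm_params(cfg.age_mean, cfg.age_sd, cfg.age_bounds)
    loc_v, scale_v = _matched_truncnorm_params(cfg.vo2_mean, cfg.vo2_sd, cfg.vo2_bounds)
    age = np.empty(0)
    vo2 = np.empty(0)
    # rejection sampling keeps the joint structure under both truncations
    while len(age) < n:
        m = max(2 * (n - len(age)), 64)
        z1 = rng.standard_normal(m)
        z2 = rho * z1 + np.sqrt(1 - rho**2) * rng.standard_normal(m)
        a = loc_a + scale_a * z1
        v = loc_v + scale_v * z2
        ok = (
            (a >= cfg.age_bounds[0])
            & (a <= cfg.age_bounds[1])
            & (v >= cfg.vo2_bounds[0])
            & (v <= cfg.vo2_bounds[1])
        )
        age = np.concatenate([age, a[ok]])
        vo2 = np.concatenate([vo2, v[ok]])
    return age[:n], vo2[:n]


def _categorical(rng: np.random.Generator, n: int, levels, probs) -> np.ndarray:
    p = np.asarray(probs, dtype=float)
    return rng.choice(np.asarray(levels, dtype=object), size=n, p=p / p.sum())


def simulate_cohort(config: ScenarioConfig) -> pd.DataFrame:
    """Draw a worker table under the scenario's demographic model.

    Returns one row per worker with the columns in :data:`WORKER_COLUMNS`.
    Identical config and seed reproduce an identical table.
    """
    config.validate()
    rng = stage_rng(config, "cohort")
    n = config.n_workers

    age, vo2 = _draw_age_fitness(rng, config, n)
    age = np.rint(age).astype(int)

    df = pd.DataFrame(
        {
            "worker_id": [f"w{i:04d}" for i in range(n)],
            "age": age,
            "sex": _categorical(rng, n, SEXES, (config.p_female, 1 - config.p_female)),
            "occupation": _categorical(rng, n, OCCUPATIONS, config.occupation_probs),
            "shift": _categorical(rng, n, SHIFTS, config.shift_probs),
            "self_rated_health": _categorical(
                rng, n, np.arange(1, len(config.health_probs) + 1), config.health_probs
            ).astype(int),
            "medication": rng.random(n) < config.p_medication,
            "steps_per_hour": (
                np.exp(config.steps_log_mean)
                if config.steps_log_sd == 0
                else np.exp(rng.normal(config.steps_log_mean, config.steps_log_sd, size=n))
            ),
            "vo2max_rel": vo2,
            "body_mass": _draw_truncated(
                rng, n, config.mass_mean, config.mass_sd, config.mass_bounds
            ),
            "n_days": _categorical(rng, n, (1, 2, 3, 4), config.days_probs).astype(int),
        },
        columns=WORKER_COLUMNS,
    )
    return df


def fitness_moments(config: ScenarioConfig) -> tuple[float, float]:
    """Population mean and variance of generated fitness.

    The generator matches its truncated draw to the configured moments, so
    these are simply (vo2_mean, vo2_sd**2).
    """
    return config.vo2_mean, config.vo2_sd**2
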