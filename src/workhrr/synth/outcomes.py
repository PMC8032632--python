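"""Metric-level outcome generation with injected fitness effects.

Each worker's outcomes follow a linear model on the generator's scale:

    hrr_mean_i     = a_m + b_m(age_i) * vo2_i + cov_m(i) + e_m,i
    hrr_max_1min_i = a_x + b_x(age_i) * vo2_i + cov_x(i) + e_x,i
    ilr_z_i        = a_z + b_z(age_i) * vo2_i + cov_z(i) + e_z,i

with the proportion of work time at or above the 30 %HRR cut-off obtained by
inverting the two-part isometric log-ratio of ``ilr_z``.  Intercepts and
residual SDs are calibrated analytically so the cohort reproduces the target
summaries (mean / SD of the two %HRR outcomes, median of the proportion)
while the slopes equal the configured effects.  The composition slope is
derived from the target percentage-point change by inverting the ilr
back-transform at the compositional median.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from ..coda_stats import ilr_inverse, ilr_two_part
from .config import (
    DEFAULT_AGE_BAND_EDGES,
    OCCUPATIONS,
    SHIFTS,
    ConfigError,
    ScenarioConfig,
    stage_rng,
)
from .cohort import fitness_moments

_OUTCOME_KEYS = ("hrr_mean", "hrr_max_1min", "ilr_z")


def derive_ilr_slope(delta_pct: float, p_ref: float) -> float:
    """ilr-scale slope whose back-transformed effect at ``p_ref`` is ``delta_pct`` points.

    Exactly inverts the +1-unit contrast used when reporting the composition
    effect: p(z_ref + b_z) - p(z_ref) = delta_pct / 100.
    """
    p_new = p_ref + delta_pct / 100.0
    if not 0.0 < p_new < 1.0:
        raise ConfigError("delta_pct pushes the reference proportion outside (0, 1)")
    return ilr_two_part(p_new) - ilr_two_part(p_ref)


def _covariate_offsets(workers: pd.DataFrame, cfg: ScenarioConfig, outcome: str) -> np.ndarray:
    eff = cfg.covariate_effects
    if outcome == "ilr_z":
        eff = eff.scaled(cfg.covariate_ilr_scale)
    occ_map = dict(zip(OCCUPATIONS, eff.occupation))
    shift_map = dict(zip(SHIFTS, eff.shift))
    out = np.where(workers["sex"].to_numpy() == "female", eff.female, 0.0)
    out = out + workers["occupation"].map(occ_map).to_numpy(dtype=float)
    out = out + workers["shift"].map(shift_map).to_numpy(dtype=float)
    return out


def _covariate_moments(cfg: ScenarioConfig, outcome: str) -> tuple[float, float]:
    """Population mean and variance of the covariate offset (independent categoricals)."""
    eff = cfg.covariate_effects
    if outcome == "ilr_z":
        eff = eff.scaled(cfg.covariate_ilr_scale)
    mean = 0.0
    var = 0.0
    for probs, offsets in (
        ((cfg.p_female, 1 - cfg.p_female), (eff.female, 0.0)),
        (cfg.occupation_probs, eff.occupation),
        (cfg.shift_probs, eff.shift),
    ):
        p = np.asarray(probs, dtype=float)
        p = p / p.sum()
        o = np.asarray(offsets, dtype=float)
        m = float(p @ o)
        mean += m
        var += float(p @ (o - m) ** 2)
    return mean, var


def _band_index(age: np.ndarray, edges: tuple[int, ...]) -> np.ndarray:
    return np.searchsorted(np.asarray(edges, dtype=float), age, side="left")


def _band_probs(cfg: ScenarioConfig, edges: tuple[int, ...]) -> np.ndarray:
    if cfg.age_sd == 0:
        p = np.zeros(len(edges) + 1)
        p[_band_index(np.array([cfg.age_mean]), edges)[0]] = 1.0
        return p
    a, b = (
        (cfg.age_bounds[0] - cfg.age_mean) / cfg.age_sd,
        (cfg.age_bounds[1] - cfg.age_mean) / cfg.age_sd,
    )
    dist = stats.truncnorm(a, b, loc=cfg.age_mean, scale=cfg.age_sd)
    cuts = np.concatenate([[cfg.age_bounds[0]], np.asarray(edges, float) + 0.5, [cfg.age_bounds[1]]])
    cdf = dist.cdf(cuts)
    return np.diff(cdf) / (cdf[-1] - cdf[0])


def _slopes(cfg: ScenarioConfig) -> dict:
    """Per-outcome slope specification: base slope, optional bands, optional gamma."""
    z_ref = ilr_two_part(cfg.prop_above_median)
    base = {
        "hrr_mean": cfg.beta_mean,
        "hrr_max_1min": cfg.beta_max,
        "ilr_z": derive_ilr_slope(cfg.delta_pct, cfg.prop_above_median),
    }
    spec = {"base": base, "bands": None, "edges": None, "gamma": {}}
    ai = cfg.age_interaction
    if ai is None:
        return spec
    if "bands" in ai:
        edges = tuple(ai.get("edges", DEFAULT_AGE_BAND_EDGES))
        bands = {}
        raw = ai["bands"]
        for key in ("hrr_mean", "hrr_max_1min"):
            bands[key] = tuple(raw.get(key, (base[key],) * (len(edges) + 1)))
        if "delta_pct" in raw:
            bands["ilr_z"] = tuple(derive_ilr_slope(d, cfg.prop_above_median) for d in raw["delta_pct"])
        else:
            bands["ilr_z"] = tuple(raw.get("ilr_z", (base["ilr_z"],) * (len(edges) + 1)))
        spec["bands"] = bands
        spec["edges"] = edges
    if "gamma" in ai:
        spec["gamma"] = dict(ai["gamma"])
    del z_ref
    return spec


def _calibration(cfg: ScenarioConfig) -> dict:
    """Intercepts and residual SDs reproducing the target cohort summaries."""
    mu_v, var_v = fitness_moments(cfg)
    spec = _slopes(cfg)
    targets = {
        "hrr_mean": (cfg.hrr_mean_target, cfg.hrr_mean_sd),
        "hrr_max_1min": (cfg.hrr_max_target, cfg.hrr_max_sd),
        "ilr_z": (ilr_two_part(cfg.prop_above_median), cfg.ilr_sd),
    }
    out = {}
    for key in _OUTCOME_KEYS:
        centre, total_sd = targets[key]
        cov_mean, cov_var = _covariate_moments(cfg, key)
        if spec["bands"] is not None:
            probs = _band_probs(cfg, spec["edges"])
            betas = np.asarray(spec["bands"][key], dtype=float)
            beta_sq = float(probs @ betas**2)
            # band-specific intercepts keep every band centred on the target
            alpha = centre - betas * mu_v - cov_mean
        else:
            beta = spec["base"][key]
            beta_sq = beta**2
            alpha = centre - beta * mu_v - cov_mean
        resid_var = total_sd**2 - beta_sq * var_v - cov_var
        if resid_var < -1e-9:
            raise ConfigError(
                f"target SD for {key} is smaller than the systematic variance it must carry"
            )
        resid_var = max(resid_var, 0.0)
        out[key] = {"alpha": alpha, "resid_sd": float(np.sqrt(resid_var)), "mu_v": mu_v}
    return out


def simulate_outcomes_metric_level(
    workers: pd.DataFrame, config: ScenarioConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw per-worker workload summaries and the noise-free ground truth.

    Returns ``(summaries, ground_truth)``.  ``summaries`` mirrors the
    pipeline's per-worker output (hrr_mean, hrr_max_1min, prop_above_30,
    work_time_valid_h, n_valid_days, valid); ``ground_truth`` holds the
    linear predictors before noise and the slopes actually injected.
    """
    config.validate()
    rng = stage_rng(config, "outcomes")
    n = len(workers)
    vo2 = workers["vo2max_rel"].to_numpy(dtype=float)
    age = workers["age"].to_numpy(dtype=float)

    spec = _slopes(config)
    calib = _calibration(config)
    mu_v = calib["hrr_mean"]["mu_v"]
    age_centre = float(
        stats.truncnorm.stats(
            (config.age_bounds[0] - config.age_mean) / config.age_sd,
            (config.age_bounds[1] - config.age_mean) / config.age_sd,
            loc=config.age_mean,
            scale=config.age_sd,
            moments="m",
        )
        if config.age_sd > 0
        else config.age_mean
    )

    lp = {}
    beta_used = {}
    for key in _OUTCOME_KEYS:
        cal = calib[key]
        if spec["bands"] is not None:
            idx = _band_index(age, spec["edges"])
            betas = np.asarray(spec["bands"][key], dtype=float)
            beta_i = betas[idx]
            alpha_i = np.asarray(cal["alpha"])[idx]
        else:
            beta_i = np.full(n, spec["base"][key])
            alpha_i = np.full(n, cal["alpha"])
        lp_k = alpha_i + beta_i * vo2 + _covariate_offsets(workers, config, key)
        gamma = spec["gamma"].get(key, 0.0)
        if gamma:
            lp_k = lp_k + gamma * (age - age_centre) * (vo2 - mu_v)
        lp[key] = lp_k
        beta_used[key] = beta_i

    corr = np.asarray(config.resid_corr, dtype=float)
    chol = np.linalg.cholesky(corr)
    eps = rng.standard_normal((n, 3)) @ chol.T
    sds = np.array([calib[k]["resid_sd"] for k in _OUTCOME_KEYS])
    eps = eps * sds

    y_mean = lp["hrr_mean"] + eps[:, 0]
    y_max = lp["hrr_max_1min"] + eps[:, 1]
    z = lp["ilr_z"] + eps[:, 2]

    summaries = pd.DataFrame(
        {
            "worker_id": workers["worker_id"].to_numpy(),
            "hrr_mean": y_mean,
            "hrr_max_1min": y_max,
            "prop_above_30": ilr_inverse(z),
            "ilr_z": z,
            "work_time_valid_h": workers["n_days"].to_numpy() * config.work_hours,
            "n_valid_days": workers["n_days"].to_numpy(),
            "valid": True,
        }
    )
    ground_truth = pd.DataFrame(
        {
            "worker_id": workers["worker_id"].to_numpy(),
            "true_hrr_mean": lp["hrr_mean"],
            "true_hrr_max_1min": lp["hrr_max_1min"],
            "true_prop_above_30": ilr_inverse(lp["ilr_z"]),
            "true_ilr_z": lp["ilr_z"],
            "beta_hrr_mean": beta_used["hrr_mean"],
            "beta_hrr_max_1min": beta_used["hrr_max_1min"],
            "beta_ilr_z": beta_used["ilr_z"],
            "seed": config.seed,
        }
    )
    return summaries, ground_truth
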