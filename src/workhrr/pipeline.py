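"""Pipeline orchestration: simulate -> qc -> workload -> fitness -> analyze.

A run writes all stage outputs under one directory and records a manifest
(config hash, derived stage seeds, file inventory, aggregate QC counts) so a
rerun with identical inputs reproduces identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import coda_stats, fitness as fitness_mod, hrr, io
from .synth import (
    ScenarioConfig,
    beat_level_ground_truth,
    simulate_cohort,
    simulate_ibi_stream,
    simulate_outcomes_metric_level,
    stage_rng,
)
from .types import WorkloadSummary

logger = logging.getLogger(__name__)

PRIMARY_OUTCOMES = ("hrr_mean", "hrr_max_1min", "ilr_z")


def load_config(path: Path) -> ScenarioConfig:
    """Build a scenario from a flat YAML mapping of config field overrides."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError("scenario config must be a mapping")
    fields = {f.name for f in dataclasses.fields(ScenarioConfig)}
    unknown = set(raw) - fields
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    for key in raw:
        if isinstance(raw[key], list):
            raw[key] = tuple(raw[key])
    cfg = ScenarioConfig(**raw)
    cfg.validate()
    return cfg


def config_hash(config: ScenarioConfig) -> str:
    blob = json.dumps(dataclasses.asdict(config), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def stage_simulate(config: ScenarioConfig, out_dir: Path) -> dict:
    out_dir.mkdir(parents=True, exist_ok=True)
    workers = simulate_cohort(config)
    io.write_workers(workers, out_dir / "workers.csv")
    summaries, truth = simulate_outcomes_metric_level(workers, config)
    files = ["workers.csv", "ground_truth.csv"]
    if config.fidelity == "metric_level":
        summaries.to_csv(out_dir / "workload_summary.csv", index=False)
        truth.to_csv(out_dir / "ground_truth.csv", index=False)
        files.append("workload_summary.csv")
    else:
        truth = beat_level_ground_truth(workers, summaries, config)
        truth.to_csv(out_dir / "ground_truth.csv", index=False)
        rng = stage_rng(config, "beats")
        diary = []
        ibi_dir = out_dir / "ibi"
        for _, w in workers.iterrows():
            t = truth[truth["worker_id"] == w["worker_id"]].iloc[0]
            series_list, ivs = simulate_ibi_stream(w, t, config, rng=rng)
            for s in series_list:
                io.write_ibi_series(s, ibi_dir)
            diary += ivs
        io.write_diary(diary, out_dir / "diary.csv")
        files += ["diary.csv", "ibi/"]
    return {"stage": "simulate", "files": files, "n_workers": len(workers)}


def stage_workload(
    in_dir: Path,
    out_dir: Path,
    max_gap_s: float = 10.0,
    cutoff: float = 30.0,
    min_duration_s: float = 60.0,
) -> dict:
    """Beat streams + diary -> per-worker workload summaries (QC included)."""
    out_dir.mkdir(parents=True, exist_ok=True)
    workers = io.read_workers(in_dir / "workers.csv")
    diary = io.read_diary(in_dir / "diary.csv")
    summaries: list[WorkloadSummary] = []
    qc_totals: dict[str, int] = {}
    for _, w in workers.iterrows():
        wid = str(w["worker_id"])
        series_by_day = {}
        for path in sorted((in_dir / "ibi").glob(f"{wid}_*.csv")):
            s = io.read_ibi_series(path)
            series_by_day[s.day] = s
        summary, report = hrr.compute_workload(
            series_by_day,
            [iv for iv in diary if iv.worker_id == wid],
            age=float(w["age"]),
            worker_id=wid,
            max_gap_s=max_gap_s,
            cutoff=cutoff,
            min_duration_s=min_duration_s,
        )
        summaries.append(summary)
        for key, val in dataclasses.asdict(report).items():
            if isinstance(val, bool):
                val = int(val)
            qc_totals[key] = qc_totals.get(key, 0) + val
    io.summaries_to_frame(summaries).to_csv(out_dir / "workload_summary.csv", index=False)
    io.write_json(qc_totals, out_dir / "qc_report.json")
    return {"stage": "workload", "files": ["workload_summary.csv", "qc_report.json"],
            "qc": qc_totals}


def stage_fitness(config: ScenarioConfig, in_dir: Path, out_dir: Path) -> dict:
    """Simulated ergometer sessions per worker -> estimated fitness table."""
    out_dir.mkdir(parents=True, exist_ok=True)
    workers = io.read_workers(in_dir / "workers.csv")
    rng = stage_rng(config, "fitness")
    rows = []
    for _, w in workers.iterrows():
        _, result = fitness_mod.simulate_test_session(w, rng=rng)
        rows.append(
            {
                "worker_id": w["worker_id"],
                "vo2max_rel_est": result.vo2max_rel,
                "steady_state": result.steady_state,
                "power_adjusted": result.power_adjusted,
                "termination_minute": result.termination_minute,
                "reason": result.reason,
            }
        )
    pd.DataFrame(rows).to_csv(out_dir / "fitness.csv", index=False)
    return {"stage": "fitness", "files": ["fitness.csv"]}


def stage_analyze(
    in_dir: Path,
    out_dir: Path,
    strata: tuple[str, ...] = ("age_quartiles", "occupation", "steps_quartiles"),
    pinned: bool = False,
    min_rows: int = 30,
) -> dict:
    out_dir.mkdir(parents=True, exist_ok=True)
    workers = io.read_workers(in_dir / "workers.csv")
    summaries = pd.read_csv(in_dir / "workload_summary.csv")
    df = coda_stats.build_analysis_table(workers, summaries)

    estimates = []
    for outcome in PRIMARY_OUTCOMES:
        for adjusted in (False, True):
            estimates.append(
                coda_stats.fit_model(df, outcome, adjusted=adjusted, min_rows=min_rows)
            )
        estimates.append(coda_stats.interaction_test(df, outcome))
        for by in strata:
            estimates += coda_stats.stratify(df, by, outcome, pinned=pinned)

    frame = coda_stats.estimates_to_frame(estimates)

    comp_rows = []
    for adjusted in (False, True):
        eff = coda_stats.backtransform_delta_pct(df, adjusted=adjusted, min_rows=min_rows)
        comp_rows.append(
            {
                "model": eff.ilr.model,
                "delta_pct": eff.delta_pct,
                "delta_ci_low": eff.delta_ci_low,
                "delta_ci_high": eff.delta_ci_high,
                "ilr_slope": eff.ilr.slope,
                "n": eff.ilr.n,
            }
        )
    frame.to_csv(out_dir / "estimates.csv", index=False)
    pd.DataFrame(comp_rows).to_csv(out_dir / "composition_effect.csv", index=False)
    io.write_json(
        {
            "n_analysed": int(len(df)),
            "strata": list(strata),
            "pinned": pinned,
            "delta_method": "back-transform at mean fitted ilr, +1 unit fitness contrast",
        },
        out_dir / "analysis.json",
    )
    return {
        "stage": "analyze",
        "files": ["estimates.csv", "composition_effect.csv", "analysis.json"],
        "n_analysed": int(len(df)),
    }


def run_pipeline(
    config: ScenarioConfig | Path | str,
    out_dir: Path | str,
    seed: Optional[int] = None,
    pinned_strata: bool = False,
    min_analysis_rows: int = 30,
) -> dict:
    """Execute all stages in order and write a run manifest."""
    if not isinstance(config, ScenarioConfig):
        config = load_config(Path(config))
    if seed is not None:
        config = config.replace(seed=int(seed))
    config.validate()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    stages = [stage_simulate(config, out_dir)]
    if config.fidelity == "beat_level":
        stages.append(stage_workload(out_dir, out_dir))
    stages.append(stage_fitness(config, out_dir, out_dir))
    stages.append(
        stage_analyze(out_dir, out_dir, pinned=pinned_strata, min_rows=min_analysis_rows)
    )

    manifest = {
        "config_hash": config_hash(config),
        "seed": config.seed,
        "fidelity": config.fidelity,
        "stages": stages,
        "files": sorted({f for s in stages for f in s["files"]}),
    }
    io.write_json(manifest, out_dir / "manifest.json")
    return manifest


def report(out_dir: Path | str) -> str:
    """Human-readable summary of the fitted estimates in a run directory."""
    out_dir = Path(out_dir)
    est_path = out_dir / "estimates.csv"
    if not est_path.exists():
        raise FileNotFoundError(f"no estimates.csv under {out_dir}; run analyze first")
    est = pd.read_csv(est_path)
    comp = pd.read_csv(out_dir / "composition_effect.csv")

    lines = ["Fitness -> aerobic workload associations (slope per 1 mlO2/min/kg)", ""]
    for outcome in PRIMARY_OUTCOMES:
        lines.append(f"[{outcome}]")
        sub = est[(est["outcome"] == outcome) & (est["stratum"].isna())]
        for _, r in sub.iterrows():
            lines.append(
                f"  {r['model']:<22} slope {r['slope']:+.3f} "
                f"[{r['ci_low']:+.3f}, {r['ci_high']:+.3f}]  p={r['p_value']:.3g}  n={r['n']}"
            )
        strat = est[(est["outcome"] == outcome) & (est["stratum"].notna())]
        for _, r in strat.iterrows():
            tag = "" if r["stable"] else "  (unstable/suppressed)"
            if np.isnan(r["slope"]):
                lines.append(f"  stratum {r['stratum']:<14} n={r['n']}  suppressed{tag}")
            else:
                lines.append(
                    f"  stratum {r['stratum']:<14} slope {r['slope']:+.3f} "
                    f"[{r['ci_low']:+.3f}, {r['ci_high']:+.3f}]  n={r['n']}{tag}"
                )
        lines.append("")
    lines.append("Composition effect (percentage points of work time per unit fitness):")
    for _, r in comp.iterrows():
        lines.append(
            f"  {r['model']:<22} delta% {r['delta_pct']:+.2f} "
            f"[{r['delta_ci_low']:+.2f}, {r['delta_ci_high']:+.2f}]  n={r['n']}"
        )
    qc_path = out_dir / "qc_report.json"
    if qc_path.exists():
        qc = json.loads(qc_path.read_text())
        lines.append("")
        lines.append("QC totals: " + ", ".join(f"{k}={v}" for k, v in sorted(qc.items())))
    return "\n".join(lines)
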