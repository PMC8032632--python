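"""Beat-level simulation: 24-h IBI streams whose derived outcomes are known.

Each simulated day follows a piecewise-constant target heart-rate profile:
a sleep trough at the worker's intended minimum heart rate, a leisure level
slightly above it, and a work block constructed from three %HRR levels — a
short high bout at the worker's target 1-min peak, a mid block at or above
the 30% cut-off and a low block below it — whose durations and levels are
solved so the derived mean %HRR, 1-min exceedance level and time-above
proportion equal the worker's ground-truth outcomes.  Beats are emitted at
60000 / HR(t) ms with optional multiplicative lognormal jitter.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from ..hrr import hr_max_tanaka
from ..types import DiaryInterval, IbiSeries
from .config import ConfigError, ScenarioConfig, stage_rng
from .cohort import _draw_truncated

_CUTOFF = 30.0


@dataclass(frozen=True)
class DayPlan:
    """Diary windows of one simulated day (seconds from day start)."""

    sleep: tuple[float, float]
    work: tuple[float, float]
    leisure: tuple[tuple[float, float], ...]

    def intervals(self, worker_id: str, day: int) -> list[DiaryInterval]:
        out = [
            DiaryInterval(worker_id, day, "sleep", *self.sleep),
            DiaryInterval(worker_id, day, "work", *self.work),
        ]
        out += [DiaryInterval(worker_id, day, "leisure", a, b) for a, b in self.leisure]
        return out

    def validate(self) -> None:
        ivs = sorted([self.sleep, self.work, *self.leisure])
        for (a0, b0), (a1, b1) in zip(ivs, ivs[1:]):
            if a1 < b0:
                raise ConfigError(f"overlapping day-plan intervals [{a0},{b0}) and [{a1},{b1})")


def make_day_plan(config: ScenarioConfig) -> DayPlan:
    s_end = config.sleep_hours * 3600.0
    w_start = config.work_start_h * 3600.0
    w_end = w_start + config.work_hours * 3600.0
    leisure = []
    if w_start > s_end:
        leisure.append((s_end, w_start))
    if w_end < 86400.0:
        leisure.append((w_end, 86400.0))
    plan = DayPlan(sleep=(0.0, s_end), work=(w_start, w_end), leisure=tuple(leisure))
    plan.validate()
    return plan


def solve_work_profile(
    g_mean: float,
    g_max: float,
    g_prop: float,
    work_s: float,
    bout_s: float = 120.0,
    low_level: float = 12.0,
) -> Optional[list[tuple[float, float]]]:
    """Durations and %HRR levels of the three-level work profile.

    Returns ``[(duration_s, pct), ...]`` whose sample mean equals ``g_mean``,
    whose highest level held >= 1 min equals ``g_max`` and whose time at or
    above the 30% cut-off is ``g_prop`` of the work block, or None when the
    targets are mutually infeasible.
    """
    t_above = g_prop * work_s
    t_bout = min(bout_s, t_above)
    t_mid = t_above - t_bout
    t_low = work_s - t_above
    if t_bout < 60.0 or g_max < _CUTOFF + 2.0 or g_max > 99.0:
        return None
    if t_mid < 1.0:
        # essentially all high-load time sits in the bout
        t_mid = 0.0
    lo_min, lo_max = 1.0, _CUTOFF - 0.5
    mid_min, mid_max = _CUTOFF + 0.5, g_max - 0.5

    def total(mid: float, low: float) -> float:
        return t_bout * g_max + t_mid * mid + t_low * low

    target = g_mean * work_s
    low = min(max(low_level, lo_min), lo_max)
    if t_mid > 0.0:
        mid = (target - t_bout * g_max - t_low * low) / t_mid
        if mid < mid_min or mid > mid_max:
            mid = min(max(mid, mid_min), mid_max)
            if t_low > 0.0:
                low = (target - t_bout * g_max - t_mid * mid) / t_low
            if low < lo_min or low > lo_max:
                return None
    else:
        if t_low == 0.0:
            return None
        low = (target - t_bout * g_max) / t_low
        if low < lo_min or low > lo_max:
            return None
        mid = mid_min  # unused (zero duration)

    segments = []
    if t_low > 0:
        segments.append((t_low / 2.0, low))
    if t_mid > 0:
        segments.append((t_mid / 2.0, mid))
    segments.append((t_bout, g_max))
    if t_mid > 0:
        segments.append((t_mid / 2.0, mid))
    if t_low > 0:
        segments.append((t_low / 2.0, low))
    return segments


def feasible_targets(
    g_mean: float, g_max: float, g_prop: float, work_s: float, bout_s: float = 120.0
) -> tuple[float, float, float]:
    """Project outcome targets into the region the profile solver can realise."""
    g_max = float(np.clip(g_max, _CUTOFF + 5.0, 95.0))
    g_prop = float(np.clip(g_prop, (bout_s + 60.0) / work_s, 0.97))
    g_max = max(g_max, g_mean + 3.0)
    # achievable mean given the clipped peak and proportion
    t_above = g_prop * work_s
    t_bout = min(bout_s, t_above)
    t_mid = t_above - t_bout
    t_low = work_s - t_above
    lo = (t_bout * g_max + t_mid * (_CUTOFF + 0.5) + t_low * 1.0) / work_s
    hi = (t_bout * g_max + t_mid * (g_max - 0.5) + t_low * (_CUTOFF - 0.5)) / work_s
    g_mean = float(np.clip(g_mean, lo + 0.01, hi - 0.01))
    return g_mean, g_max, g_prop


def _hr_at_pct(pct: float, hr_min: float, hr_max: float) -> float:
    return hr_min + pct / 100.0 * (hr_max - hr_min)


def _emit_segment_beats(
    t0: float, t1: float, hr: float, jitter_sd: float, rng: Optional[np.random.Generator]
) -> np.ndarray:
    """Beat times in (t0, t1] at rate ``hr`` starting one interval after t0."""
    ibi = 60.0 / hr
    if jitter_sd <= 0 or rng is None:
        n = int(np.floor((t1 - t0) / ibi))
        return t0 + ibi * np.arange(1, n + 1)
    n_draw = int(np.ceil((t1 - t0) / ibi * (1.0 + 5.0 * jitter_sd))) + 8
    factors = rng.lognormal(mean=-0.5 * jitter_sd**2, sigma=jitter_sd, size=n_draw)
    times = t0 + np.cumsum(ibi * factors)
    return times[times <= t1]


def emit_beats(
    profile: Sequence[tuple[float, float, float]],
    jitter_sd: float = 0.0,
    rng: Optional[np.random.Generator] = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Beat times and IBIs for a piecewise-constant HR profile.

    ``profile`` is a list of (start_s, end_s, hr_bpm) segments, contiguous and
    ordered.  Returns (time_s, ibi_ms) with ibi the difference to the
    previous beat (first beat: time since segment start).
    """
    times = []
    cursor = None
    for t0, t1, hr in profile:
        start = t0 if cursor is None else max(cursor, t0)
        seg = _emit_segment_beats(start, t1, hr, jitter_sd, rng)
        if len(seg):
            times.append(seg)
            cursor = seg[-1]
    if not times:
        return np.empty(0), np.empty(0)
    t = np.concatenate(times)
    ibi_ms = np.diff(t, prepend=profile[0][0]) * 1000.0
    return t, ibi_ms


def build_day_profile(
    plan: DayPlan,
    hr_min: float,
    hr_max: float,
    g_mean: float,
    g_max: float,
    g_prop: float,
    leisure_pct: float,
    bout_s: float = 120.0,
) -> list[tuple[float, float, float]]:
    """Full-day (start, end, HR) segments realising the worker's targets."""
    work_s = plan.work[1] - plan.work[0]
    segments = solve_work_profile(g_mean, g_max, g_prop, work_s, bout_s=bout_s)
    if segments is None:
        raise ConfigError(
            f"work profile infeasible for targets mean={g_mean}, max={g_max}, prop={g_prop}"
        )
    profile = [(plan.sleep[0], plan.sleep[1], hr_min)]
    pre = [iv for iv in plan.leisure if iv[0] < plan.work[0]]
    post = [iv for iv in plan.leisure if iv[0] >= plan.work[0]]
    leisure_hr = _hr_at_pct(leisure_pct, hr_min, hr_max)
    for a, b in pre:
        profile.append((a, b, leisure_hr))
    t = plan.work[0]
    for dur, pct in segments:
        profile.append((t, t + dur, _hr_at_pct(pct, hr_min, hr_max)))
        t += dur
    for a, b in post:
        profile.append((a, b, leisure_hr))
    return profile


def simulate_ibi_stream(
    worker: pd.Series,
    truth: pd.Series,
    config: ScenarioConfig,
    rng: Optional[np.random.Generator] = None,
) -> tuple[list[IbiSeries], list[DiaryInterval]]:
    """Emit the worker's measured days as beat streams plus diary intervals.

    ``truth`` must carry hr_min plus the realised outcome targets
    (hrr_mean / hrr_max_1min / prop_above_30 columns).
    """
    if rng is None:
        rng = stage_rng(config, "beats")
    plan = make_day_plan(config)
    hr_min = float(truth["hr_min"])
    hr_max = hr_max_tanaka(float(worker["age"]))
    profile = build_day_profile(
        plan,
        hr_min,
        hr_max,
        float(truth["true_hrr_mean"]),
        float(truth["true_hrr_max_1min"]),
        float(truth["true_prop_above_30"]),
        config.leisure_hrr_pct,
        bout_s=config.bout_s,
    )
    series = []
    diary = []
    for day in range(int(worker["n_days"])):
        t, ibi_ms = emit_beats(profile, jitter_sd=config.beat_jitter_sd, rng=rng)
        series.append(
            IbiSeries(
                worker_id=str(worker["worker_id"]),
                day=day,
                time_s=t,
                ibi_ms=ibi_ms,
                error_flag=np.zeros(len(t), dtype=bool),
            )
        )
        diary += plan.intervals(str(worker["worker_id"]), day)
    return series, diary


def beat_level_ground_truth(
    workers: pd.DataFrame, summaries: pd.DataFrame, config: ScenarioConfig
) -> pd.DataFrame:
    """Achievable per-worker targets and sleep-trough HR for beat-level runs.

    Metric-level draws are projected into the profile solver's feasible
    region; the projected values are the ground truth the emitted streams
    realise.
    """
    rng = stage_rng(config, "beats")
    work_s = config.work_hours * 3600.0
    hr_min = _draw_truncated(
        rng, len(workers), config.hr_min_mean, config.hr_min_sd, config.hr_min_bounds
    )
    rows = []
    for (_, w), (_, s), hm in zip(workers.iterrows(), summaries.iterrows(), hr_min):
        g_mean, g_max, g_prop = feasible_targets(
            float(s["hrr_mean"]), float(s["hrr_max_1min"]), float(s["prop_above_30"]),
            work_s, bout_s=config.bout_s,
        )
        rows.append(
            {
                "worker_id": w["worker_id"],
                "true_hrr_mean": g_mean,
                "true_hrr_max_1min": g_max,
                "true_prop_above_30": g_prop,
                "hr_min": float(hm),
                "seed": config.seed,
            }
        )
    return pd.DataFrame(rows)
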