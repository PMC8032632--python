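"""Heart-rate-reserve outcomes from cleaned heart-rate signals.

The relative aerobic load of a working heart rate HR is its position in the
individual span between resting and maximal heart rate (Karvonen):

    %HRR = 100 * (HR - HRmin) / (HRmax - HRmin)

HRmin is the minimum 10-beat moving-average heart rate over the whole
(multi-day) measurement — in 24-h recordings the sleeping trough, a more
stable anchor than a clinic resting measurement.  HRmax is age-predicted by
the Tanaka equation, 208 - 0.7 * age.

Three per-worker outcomes are pooled over valid days: the mean %HRR during
work, the highest %HRR level at or above which at least one cumulative
minute of work time was spent, and the proportion of work time at or above
the 30 %HRR cut-off.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from .types import DiaryInterval, HrSeries4Hz, IbiSeries, QcReport, WorkloadSummary

CUTOFF_PCT = 30.0
MIN_EXCEEDANCE_S = 60.0


class InsufficientData(ValueError):
    """Raised when a measurement cannot support the requested quantity."""


@dataclass(frozen=True)
class HrrParams:
    """Anchors of the individual heart-rate span."""

    hr_min: float
    hr_max: float
    hr_min_source: str = "measured"
    hr_max_source: str = "tanaka"

    def __post_init__(self) -> None:
        if not self.hr_max > self.hr_min > 0:
            raise ValueError("require hr_max > hr_min > 0")


def hr_max_tanaka(age: float) -> float:
    """Age-predicted maximal heart rate: 208 - 0.7 * age."""
    if age <= 0:
        raise ValueError("age must be positive")
    return 208.0 - 0.7 * age


def hr_min_10beat(hr_bpm: np.ndarray, window: int = 10) -> float:
    """Minimum of the moving 10-beat mean of instantaneous HR.

    ``hr_bpm`` is the concatenated cleaned beat-wise HR over the whole
    measurement period (all days pooled); the window averages instantaneous
    heart rate, not intervals.
    """
    hr = np.asarray(hr_bpm, dtype=float)
    if len(hr) < window:
        raise InsufficientData(f"need at least {window} beats, have {len(hr)}")
    kernel = np.ones(window) / window
    means = np.convolve(hr, kernel, mode="valid")
    return float(means.min())


def percent_hrr(hr_bpm, params: HrrParams, report: Optional[QcReport] = None):
    """Karvonen relative load, clamped to [0, 100].

    Clamp events (work HR below the measured minimum or above the predicted
    maximum) are counted into ``report`` when given.
    """
    span = params.hr_max - params.hr_min
    raw = 100.0 * (np.asarray(hr_bpm, dtype=float) - params.hr_min) / span
    lo = raw < 0.0
    hi = raw > 100.0
    if report is not None:
        report.n_clamped_low += int(np.count_nonzero(lo))
        report.n_clamped_high += int(np.count_nonzero(hi))
    out = np.clip(raw, 0.0, 100.0)
    return float(out) if np.isscalar(hr_bpm) else out


def exceedance_max(
    pct_samples: np.ndarray,
    min_duration_s: float = MIN_EXCEEDANCE_S,
    fs: float = 4.0,
) -> Optional[float]:
    """Highest level held for at least ``min_duration_s`` of cumulative time.

    Computed as the value at rank ceil(min_duration_s * fs) of the valid
    samples sorted descending; time need not be contiguous.  Returns None
    when less than ``min_duration_s`` of valid samples exist.
    """
    x = np.asarray(pct_samples, dtype=float)
    k = math.ceil(min_duration_s * fs)
    if len(x) < k:
        return None
    return float(np.partition(x, len(x) - k)[len(x) - k])


def time_composition(
    pct_samples: np.ndarray, cutoff: float = CUTOFF_PCT, dt: float = 0.25
) -> tuple[float, float]:
    """Valid work time (s) at-or-above and below the cut-off; closes exactly."""
    x = np.asarray(pct_samples, dtype=float)
    above = int(np.count_nonzero(x >= cutoff))
    return above * dt, (len(x) - above) * dt


def day_validity(
    valid_work_s_by_day: Mapping[int, float],
    diary_work_h_by_day: Mapping[int, float],
    min_hours: float = 4.0,
    frac_of_usual: float = 0.75,
) -> tuple[dict[int, bool], bool]:
    """Valid-day rule: >= 4 h of work-period HR, or >= 75% of usual work hours.

    'Usual' is the worker's mean diary work duration across measured days.
    The worker is valid when at least one day is valid.
    """
    if not diary_work_h_by_day:
        return {}, False
    usual_h = float(np.mean(list(diary_work_h_by_day.values())))
    flags = {}
    for day, diary_h in diary_work_h_by_day.items():
        got_h = valid_work_s_by_day.get(day, 0.0) / 3600.0
        flags[day] = got_h >= min_hours or got_h >= frac_of_usual * usual_h
    return flags, any(flags.values())


def summarize_worker(
    worker_id: str,
    work_pct_by_day: Mapping[int, np.ndarray],
    diary_work_h_by_day: Mapping[int, float],
    cutoff: float = CUTOFF_PCT,
    min_duration_s: float = MIN_EXCEEDANCE_S,
    dt: float = 0.25,
) -> WorkloadSummary:
    """Pool valid-day work samples into the three per-worker outcomes.

    Pooling is sample-weighted: every valid 4 Hz work sample counts equally,
    so longer valid days contribute proportionally more.
    """
    if not diary_work_h_by_day:
        return WorkloadSummary(worker_id, None, None, None, 0.0, 0, False,
                               reason="no diary work periods")
    valid_s = {d: len(x) * dt for d, x in work_pct_by_day.items()}
    flags, worker_valid = day_validity(valid_s, diary_work_h_by_day)
    if not worker_valid:
        return WorkloadSummary(worker_id, None, None, None, 0.0, 0, False,
                               reason="no valid day")
    pooled = np.concatenate(
        [np.asarray(work_pct_by_day[d], dtype=float) for d, ok in sorted(flags.items()) if ok
         and d in work_pct_by_day]
    )
    if pooled.size == 0:
        return WorkloadSummary(worker_id, None, None, None, 0.0, 0, False,
                               reason="no valid work samples")
    t_above, t_below = time_composition(pooled, cutoff=cutoff, dt=dt)
    return WorkloadSummary(
        worker_id=worker_id,
        hrr_mean=float(pooled.mean()),
        hrr_max_1min=exceedance_max(pooled, min_duration_s=min_duration_s, fs=1.0 / dt),
        prop_above_30=t_above / (t_above + t_below),
        work_time_valid_h=pooled.size * dt / 3600.0,
        n_valid_days=sum(flags.values()),
        valid=True,
    )


def compute_workload(
    series_by_day: Mapping[int, IbiSeries],
    diary: Sequence[DiaryInterval],
    age: float,
    worker_id: str,
    max_gap_s: float = 10.0,
    cutoff: float = CUTOFF_PCT,
    min_duration_s: float = MIN_EXCEEDANCE_S,
) -> tuple[WorkloadSummary, QcReport]:
    """Raw beats to WorkloadSummary for one worker: clean, anchor, resample, pool.

    HRmin is computed once from the cleaned beats of the whole measurement
    period; each day is then resampled, split by the diary and converted to
    %HRR before the valid-day rule and pooling.
    """
    from . import ibi_qc  # local import to keep module surfaces independent

    report = QcReport()
    cleaned: dict[int, IbiSeries] = {}
    for day, series in sorted(series_by_day.items()):
        s, r = ibi_qc.clean_series(series)
        report = report.merged(r)
        cleaned[day] = s

    pooled_hr = np.concatenate(
        [s.hr_bpm for s in cleaned.values() if s.valid and len(s)] or [np.empty(0)]
    )
    diary_work_h: dict[int, float] = {}
    for iv in diary:
        if iv.worker_id == worker_id and iv.period == "work":
            diary_work_h[iv.day] = diary_work_h.get(iv.day, 0.0) + (iv.end_s - iv.start_s) / 3600.0

    try:
        hr_min = hr_min_10beat(pooled_hr)
    except InsufficientData:
        return (
            WorkloadSummary(worker_id, None, None, None, 0.0, 0, False,
                            reason="fewer than 10 retained beats"),
            report,
        )
    params = HrrParams(hr_min=hr_min, hr_max=hr_max_tanaka(age))

    work_pct: dict[int, np.ndarray] = {}
    for day, s in cleaned.items():
        if not s.valid:
            continue
        hr4 = ibi_qc.resample_4hz(s, max_gap_s=max_gap_s)
        if len(hr4) == 0:
            continue
        day_diary = [iv for iv in diary if iv.worker_id == worker_id and iv.day == day]
        periods = ibi_qc.split_by_diary(hr4, day_diary)
        work = periods.get("work")
        if work is None:
            continue
        samples = work.hr_bpm[work.valid]
        work_pct[day] = percent_hrr(samples, params, report=report)

    summary = summarize_worker(
        worker_id, work_pct, diary_work_h, cutoff=cutoff, min_duration_s=min_duration_s
    )
    return summary, report
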