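"""Quality control for raw inter-beat-interval streams.

Cleaning cascade, applied in this order:

1. physiological range — beats whose instantaneous rate falls below 36 or
   above 200 beats/min are discarded (boundary values retained);
2. neighbour deviation — isolated beats differing by more than 15% from both
   adjacent beats are discarded (device ectopics / missed triggers);
3. beat-error exclusion — 60-s epochs whose device-flagged beat fraction
   exceeds 50% are dropped, and a whole measurement whose overall flagged
   fraction exceeds 50% is marked invalid;
4. resampling — instantaneous heart rate anchored at beat times is linearly
   interpolated onto a 4 Hz grid, with samples inside long beat gaps masked.

The neighbour rule uses the symmetric relative difference
|a - b| / ((a + b) / 2); with this base the filter is idempotent, which a
one-sided percentage base is not.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np

from .types import DiaryInterval, HrSeries4Hz, IbiSeries, QcReport

HR_LO_BPM = 36.0
HR_HI_BPM = 200.0


def filter_hr_range(
    series: IbiSeries, lo_bpm: float = HR_LO_BPM, hi_bpm: float = HR_HI_BPM
) -> tuple[IbiSeries, QcReport]:
    """Discard beats with instantaneous HR strictly below ``lo_bpm`` or above ``hi_bpm``."""
    report = QcReport(n_input=len(series))
    if len(series) == 0:
        return series, report
    hr = series.hr_bpm
    keep = (hr >= lo_bpm) & (hr <= hi_bpm)
    report.n_removed_range = int((~keep).sum())
    return series.take(keep), report


def _sym_rel_diff(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    return np.abs(a - b) / ((a + b) / 2.0)


def filter_neighbor_deviation(
    series: IbiSeries, tol: float = 0.15, mode: str = "isolated"
) -> tuple[IbiSeries, QcReport]:
    """Discard beats deviating by more than ``tol`` from their neighbours.

    ``mode='isolated'`` (default): an interior beat is discarded only when it
    deviates from *both* adjacent beats; the first and last beats are judged
    against their single neighbour.  ``mode='previous'`` is the one-sided
    variant comparing each beat to its predecessor only.
    """
    report = QcReport(n_input=len(series))
    if len(series) < 2:
        return series, report
    x = series.ibi_ms
    d = _sym_rel_diff(x[:-1], x[1:])  # d[i] between beats i and i+1
    exceeds_prev = np.concatenate([[False], d > tol])
    exceeds_next = np.concatenate([d > tol, [False]])
    if mode == "isolated":
        remove = exceeds_prev & exceeds_next
        remove[0] = exceeds_next[0]
        remove[-1] = exceeds_prev[-1]
    elif mode == "previous":
        remove = exceeds_prev
    else:
        raise ValueError(f"unknown neighbour mode {mode!r}")
    report.n_removed_neighbor = int(remove.sum())
    return series.take(~remove), report


def exclude_by_beat_error(
    series: IbiSeries, epoch_s: float = 60.0, max_rate: float = 0.5
) -> tuple[IbiSeries, QcReport]:
    """Drop epochs whose flagged-beat fraction exceeds ``max_rate``.

    If the whole measurement's flagged fraction exceeds ``max_rate`` the
    series is marked invalid (beats retained for inspection, ``valid=False``).
    """
    report = QcReport(n_input=len(series))
    if len(series) == 0:
        return series, report
    overall = float(series.error_flag.mean())
    if overall > max_rate:
        report.series_invalid = True
        return series.mark_invalid(), report
    epoch = np.floor(series.time_s / epoch_s).astype(np.int64)
    # per-epoch flagged fraction over the epochs that contain beats
    uniq, inverse = np.unique(epoch, return_inverse=True)
    flagged = np.bincount(inverse, weights=series.error_flag.astype(float))
    counts = np.bincount(inverse)
    bad_epoch = flagged / counts > max_rate
    remove = bad_epoch[inverse]
    report.n_removed_epoch_error = int(remove.sum())
    report.n_epochs_excluded = int(bad_epoch.sum())
    return series.take(~remove), report


def resample_4hz(series: IbiSeries, max_gap_s: float = 10.0) -> HrSeries4Hz:
    """Linear interpolation of instantaneous HR onto a 4 Hz grid.

    Samples falling inside beat gaps longer than ``max_gap_s`` are masked:
    interpolating across a long dropout would manufacture data.  With fewer
    than two beats the series is fully masked.
    """
    dt = 0.25
    if len(series) < 2:
        start = float(series.time_s[0]) if len(series) else 0.0
        return HrSeries4Hz(start_s=start, hr_bpm=np.empty(0), valid=np.empty(0, dtype=bool))
    t = series.time_s
    hr = series.hr_bpm
    start = np.ceil(t[0] / dt) * dt
    n = int(np.floor((t[-1] - start) / dt)) + 1
    if n <= 0:
        return HrSeries4Hz(start_s=float(t[0]), hr_bpm=np.empty(0), valid=np.empty(0, dtype=bool))
    grid = start + np.arange(n) * dt
    values = np.interp(grid, t, hr)
    right = np.searchsorted(t, grid, side="left")
    right = np.clip(right, 1, len(t) - 1)
    gap = t[right] - t[right - 1]
    valid = gap <= max_gap_s
    if not series.valid:
        valid = np.zeros_like(valid)
    return HrSeries4Hz(start_s=float(start), hr_bpm=values, valid=valid)


def validate_diary(intervals: Sequence[DiaryInterval]) -> None:
    """Raise if any two intervals of the same worker-day overlap."""
    by_day: dict[tuple[str, int], list[DiaryInterval]] = {}
    for iv in intervals:
        by_day.setdefault((iv.worker_id, iv.day), []).append(iv)
    for (_, _), ivs in by_day.items():
        ivs = sorted(ivs, key=lambda iv: iv.start_s)
        for prev, cur in zip(ivs, ivs[1:]):
            if cur.start_s < prev.end_s:
                raise ValueError(
                    f"overlapping diary intervals for {cur.worker_id} day {cur.day}: "
                    f"{prev.period} [{prev.start_s}, {prev.end_s}) and "
                    f"{cur.period} [{cur.start_s}, {cur.end_s})"
                )


def assign_periods(hr: HrSeries4Hz, intervals: Sequence[DiaryInterval]) -> np.ndarray:
    """Diary period label per 4 Hz sample ('uncovered' outside every interval).

    Intervals are half-open [start, end): a sample exactly at an interval end
    belongs to the next period, not this one.
    """
    validate_diary(intervals)
    t = hr.time_s
    labels = np.full(len(t), "uncovered", dtype=object)
    for iv in intervals:
        labels[(t >= iv.start_s) & (t < iv.end_s)] = iv.period
    return labels


def split_by_diary(
    hr: HrSeries4Hz, intervals: Sequence[DiaryInterval]
) -> dict[str, HrSeries4Hz]:
    """Per-period views of the 4 Hz series (same grid, membership-restricted masks)."""
    labels = assign_periods(hr, intervals)
    out = {}
    for period in sorted({iv.period for iv in intervals} | {"uncovered"}):
        out[period] = hr.with_mask(labels == period)
    return out


def clean_series(
    series: IbiSeries,
    tol: float = 0.15,
    neighbor_mode: str = "isolated",
    epoch_s: float = 60.0,
    max_error_rate: float = 0.5,
) -> tuple[IbiSeries, QcReport]:
    """Full cleaning cascade: range, neighbour deviation, beat-error exclusion."""
    s1, r1 = filter_hr_range(series)
    s2, r2 = filter_neighbor_deviation(s1, tol=tol, mode=neighbor_mode)
    s3, r3 = exclude_by_beat_error(s2, epoch_s=epoch_s, max_rate=max_error_rate)
    report = QcReport(
        n_input=len(series),
        n_removed_range=r1.n_removed_range,
        n_removed_neighbor=r2.n_removed_neighbor,
        n_removed_epoch_error=r3.n_removed_epoch_error,
        n_epochs_excluded=r3.n_epochs_excluded,
        series_invalid=r3.series_invalid,
    )
    return s3, report
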