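"""Shared domain containers for the workload pipeline.

The pipeline moves data through three representations: a raw beat stream
(:class:`IbiSeries`), a uniformly resampled heart-rate signal
(:class:`HrSeries4Hz`) and per-worker outcome summaries
(:class:`WorkloadSummary`).  Diary intervals (:class:`DiaryInterval`) bound
the analysis windows; model output is carried in :class:`EffectEstimate`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

PERIODS = ("work", "leisure", "sleep", "nonwear")


@dataclass
class IbiSeries:
    """One day of beat-level data for one worker.

    ``time_s`` holds beat timestamps in seconds from local day start and must
    be strictly increasing; ``ibi_ms`` is the recorded inter-beat interval in
    milliseconds (device artifacts may make it disagree with the timestamp
    difference); ``error_flag`` marks beats the device reported as unreliable.
    """

    worker_id: str
    day: int
    time_s: np.ndarray
    ibi_ms: np.ndarray
    error_flag: np.ndarray
    valid: bool = True

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.ibi_ms = np.asarray(self.ibi_ms, dtype=float)
        self.error_flag = np.asarray(self.error_flag, dtype=bool)
        n = len(self.time_s)
        if len(self.ibi_ms) != n or len(self.error_flag) != n:
            raise ValueError("time_s, ibi_ms and error_flag must have equal length")
        if n and np.any(np.diff(self.time_s) <= 0):
            raise ValueError("beat times must be strictly increasing")
        if n and np.any(self.ibi_ms <= 0):
            raise ValueError("inter-beat intervals must be positive")

    def __len__(self) -> int:
        return len(self.time_s)

    @property
    def hr_bpm(self) -> np.ndarray:
        """Instantaneous heart rate, 60000 / IBI(ms)."""
        return 60000.0 / self.ibi_ms

    def take(self, keep: np.ndarray) -> "IbiSeries":
        """Subset by boolean mask or index array, preserving order."""
        return IbiSeries(
            worker_id=self.worker_id,
            day=self.day,
            time_s=self.time_s[keep],
            ibi_ms=self.ibi_ms[keep],
            error_flag=self.error_flag[keep],
            valid=self.valid,
        )

    def mark_invalid(self) -> "IbiSeries":
        out = self.take(np.ones(len(self), dtype=bool))
        out.valid = False
        return out


@dataclass(frozen=True)
class DiaryInterval:
    """A diary-labelled period bounding an analysis window; half-open [start, end)."""

    worker_id: str
    day: int
    period: str
    start_s: float
    end_s: float

    def __post_init__(self) -> None:
        if self.period not in PERIODS:
            raise ValueError(f"unknown diary period {self.period!r}")
        if not self.end_s > self.start_s:
            raise ValueError("diary interval must have end_s > start_s")


@dataclass
class HrSeries4Hz:
    """Heart rate resampled on a uniform 4 Hz grid with a per-sample validity mask."""

    start_s: float
    hr_bpm: np.ndarray
    valid: np.ndarray

    FS: float = field(default=4.0, repr=False)

    def __post_init__(self) -> None:
        self.hr_bpm = np.asarray(self.hr_bpm, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        if len(self.hr_bpm) != len(self.valid):
            raise ValueError("hr_bpm and valid must have equal length")

    @property
    def dt(self) -> float:
        return 1.0 / self.FS

    def __len__(self) -> int:
        return len(self.hr_bpm)

    @property
    def time_s(self) -> np.ndarray:
        return self.start_s + np.arange(len(self.hr_bpm)) * self.dt

    def with_mask(self, mask: np.ndarray) -> "HrSeries4Hz":
        """Same grid, validity restricted to ``mask``."""
        return HrSeries4Hz(self.start_s, self.hr_bpm, self.valid & mask)


@dataclass
class QcReport:
    """Book-keeping for the cleaning cascade on one beat series."""

    n_input: int = 0
    n_removed_range: int = 0
    n_removed_neighbor: int = 0
    n_removed_epoch_error: int = 0
    n_epochs_excluded: int = 0
    series_invalid: bool = False
    n_clamped_low: int = 0
    n_clamped_high: int = 0

    @property
    def n_retained(self) -> int:
        return (
            self.n_input
            - self.n_removed_range
            - self.n_removed_neighbor
            - self.n_removed_epoch_error
        )

    @property
    def fraction_retained(self) -> float:
        return self.n_retained / self.n_input if self.n_input else 0.0

    def merged(self, other: "QcReport") -> "QcReport":
        return QcReport(
            n_input=self.n_input + other.n_input,
            n_removed_range=self.n_removed_range + other.n_removed_range,
            n_removed_neighbor=self.n_removed_neighbor + other.n_removed_neighbor,
            n_removed_epoch_error=self.n_removed_epoch_error + other.n_removed_epoch_error,
            n_epochs_excluded=self.n_epochs_excluded + other.n_epochs_excluded,
            series_invalid=self.series_invalid or other.series_invalid,
            n_clamped_low=self.n_clamped_low + other.n_clamped_low,
            n_clamped_high=self.n_clamped_high + other.n_clamped_high,
        )


@dataclass
class WorkloadSummary:
    """Per-worker aerobic workload outcomes pooled over valid days."""

    worker_id: str
    hrr_mean: Optional[float]
    hrr_max_1min: Optional[float]
    prop_above_30: Optional[float]
    work_time_valid_h: float
    n_valid_days: int
    valid: bool
    reason: str = ""


@dataclass
class EffectEstimate:
    """One regression coefficient: slope per 1 mlO2/min/kg of fitness."""

    model: str
    outcome: str
    term: str
    slope: float
    ci_low: float
    ci_high: float
    p_value: float
    n: int
    stratum: Optional[str] = None
    stable: bool = True


@dataclass
class CompositionEffect:
    """An ilr-scale slope and its back-transformed absolute change in work-time share."""

    ilr: EffectEstimate
    delta_pct: float
    delta_ci_low: float
    delta_ci_high: float


__all__ = [
    "PERIODS",
    "IbiSeries",
    "DiaryInterval",
    "HrSeries4Hz",
    "QcReport",
    "WorkloadSummary",
    "EffectEstimate",
    "CompositionEffect",
    "replace",
]
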