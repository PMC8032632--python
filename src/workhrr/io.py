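"""CSV/JSON persistence for every pipeline stage.

All tabular output is plain CSV with headers; beat streams are written one
file per worker-day under ``ibi/`` with columns time_s, ibi_ms, error_flag.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .types import DiaryInterval, IbiSeries, WorkloadSummary


def write_workers(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False)


def read_workers(path: Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    df["medication"] = df["medication"].astype(bool)
    return df


def write_ibi_series(series: IbiSeries, directory: Path) -> Path:
    directory.mkdir(parents=True, exist_ok=True)
    path = directory / f"{series.worker_id}_{series.day}.csv"
    pd.DataFrame(
        {
            "time_s": series.time_s,
            "ibi_ms": series.ibi_ms,
            "error_flag": series.error_flag.astype(int),
        }
    ).to_csv(path, index=False, float_format="%.4f")
    return path


def read_ibi_series(path: Path) -> IbiSeries:
    worker_id, day = path.stem.rsplit("_", 1)
    df = pd.read_csv(path)
    return IbiSeries(
        worker_id=worker_id,
        day=int(day),
        time_s=df["time_s"].to_numpy(float),
        ibi_ms=df["ibi_ms"].to_numpy(float),
        error_flag=df["error_flag"].to_numpy(bool),
    )


def write_diary(intervals: Sequence[DiaryInterval], path: Path) -> None:
    pd.DataFrame(
        [
            {
                "worker_id": iv.worker_id,
                "day": iv.day,
                "period": iv.period,
                "start_s": iv.start_s,
                "end_s": iv.end_s,
            }
            for iv in intervals
        ]
    ).to_csv(path, index=False)


def read_diary(path: Path) -> list[DiaryInterval]:
    df = pd.read_csv(path)
    return [
        DiaryInterval(str(r.worker_id), int(r.day), str(r.period), float(r.start_s), float(r.end_s))
        for r in df.itertuples()
    ]


def summaries_to_frame(summaries: Iterable[WorkloadSummary]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "worker_id": s.worker_id,
                "hrr_mean": s.hrr_mean,
                "hrr_max_1min": s.hrr_max_1min,
                "prop_above_30": s.prop_above_30,
                "work_time_valid_h": s.work_time_valid_h,
                "n_valid_days": s.n_valid_days,
                "valid": s.valid,
                "reason": s.reason,
            }
            for s in summaries
        ]
    )


def write_json(obj: dict, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=_jsonify) + "\n")


def _jsonify(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    if isinstance(x, np.ndarray):
        return x.tolist()
    raise TypeError(f"not JSON serialisable: {type(x)}")
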