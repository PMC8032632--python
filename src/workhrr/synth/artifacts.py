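"""Controlled contamination of beat streams to exercise every QC rule."""

from __future__ import annotations

from typing import Optional

import numpy as np
import pandas as pd

from ..types import IbiSeries
from .config import ArtifactConfig, ScenarioConfig, stage_rng

# replacement intervals clearly outside the 36-200 bpm physiological band
_OOR_IBI_MS = (2400.0, 280.0)  # 25 bpm, ~214 bpm
_ECTOPIC_FACTORS = (1.35, 0.72)  # >15% deviation on both sides


def _spaced_positions(
    rng: np.random.Generator, n_beats: int, n_wanted: int, taken: set[int], min_gap: int = 3
) -> list[int]:
    """Interior beat indices with pairwise spacing, avoiding already-taken slots."""
    if n_wanted <= 0 or n_beats < 2 * min_gap + 1:
        return []
    candidates = rng.permutation(np.arange(min_gap, n_beats - min_gap))
    chosen: list[int] = []
    blocked = set(taken)
    for idx in candidates:
        if len(chosen) >= n_wanted:
            break
        if any((idx + d) in blocked for d in range(-min_gap, min_gap + 1)):
            continue
        chosen.append(int(idx))
        for d in range(-min_gap, min_gap + 1):
            blocked.add(idx + d)
    return sorted(chosen)


def inject_artifacts(
    series: IbiSeries,
    artifact_config: ArtifactConfig,
    rng: Optional[np.random.Generator] = None,
    config: Optional[ScenarioConfig] = None,
) -> tuple[IbiSeries, pd.DataFrame]:
    """Contaminate a beat stream at the configured rates.

    Injects out-of-range interval values, isolated ectopic beats (interval
    scaled by >15% with untouched neighbours), runs of device-flagged beats
    and non-wear gaps (beats deleted).  Returns the contaminated series and
    an injection log (columns: kind, time_s, index, detail).  All rates zero
    returns the input unchanged.
    """
    artifact_config.validate()
    if rng is None:
        rng = stage_rng(config, "artifacts") if config is not None else np.random.default_rng(0)

    n = len(series)
    time_s = series.time_s.copy()
    ibi_ms = series.ibi_ms.copy()
    flags = series.error_flag.copy()
    log_rows: list[dict] = []
    taken: set[int] = set()

    n_oor = int(round(artifact_config.out_of_range_rate * n))
    for j, idx in enumerate(_spaced_positions(rng, n, n_oor, taken)):
        ibi_ms[idx] = _OOR_IBI_MS[j % 2]
        taken.add(idx)
        log_rows.append(
            {"kind": "out_of_range", "time_s": time_s[idx], "index": idx,
             "detail": f"ibi_ms={ibi_ms[idx]:g}"}
        )

    n_ect = int(round(artifact_config.ectopic_rate * n))
    for j, idx in enumerate(_spaced_positions(rng, n, n_ect, taken)):
        factor = _ECTOPIC_FACTORS[j % 2]
        ibi_ms[idx] = ibi_ms[idx] * factor
        taken.add(idx)
        log_rows.append(
            {"kind": "ectopic", "time_s": time_s[idx], "index": idx, "detail": f"factor={factor}"}
        )

    n_flagged = int(round(artifact_config.error_flag_rate * n))
    run = max(1, artifact_config.error_run_beats)
    n_runs = max(1, n_flagged // run) if n_flagged else 0
    for _ in range(n_runs):
        start = int(rng.integers(0, max(1, n - run)))
        flags[start : start + run] = True
        log_rows.append(
            {"kind": "error_run", "time_s": time_s[start], "index": start, "detail": f"beats={run}"}
        )

    keep = np.ones(n, dtype=bool)
    for _ in range(artifact_config.n_nonwear_gaps):
        if n < 10:
            break
        start_idx = int(rng.integers(1, n - 1))
        t0 = time_s[start_idx]
        t1 = t0 + artifact_config.nonwear_gap_s
        keep &= ~((time_s >= t0) & (time_s < t1))
        log_rows.append(
            {"kind": "nonwear_gap", "time_s": t0, "index": start_idx,
             "detail": f"until_s={t1:g}"}
        )

    out = IbiSeries(
        worker_id=series.worker_id,
        day=series.day,
        time_s=time_s[keep],
        ibi_ms=ibi_ms[keep],
        error_flag=flags[keep],
        valid=series.valid,
    )
    log = pd.DataFrame(log_rows, columns=["kind", "time_s", "index", "detail"])
    return out, log
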