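"""Association analysis: compositional outcome, linear models, interaction, strata.

The two-part composition of work time (at-or-above vs below the 30 %HRR
cut-off) is carried into the models as its isometric log-ratio balance

    z = (1 / sqrt(2)) * ln(p_above / p_below),

so that ordinary least squares on z respects the unit-sum constraint of the
composition.  Fitness slopes for the two %HRR outcomes are reported directly;
the composition slope is back-transformed to an absolute change in the
percentage of work time, evaluated at the fitted compositional mean with a
+1 mlO2/min/kg contrast.
"""

from __future__ import annotations

import logging
import math
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from scipy.special import expit

from .types import CompositionEffect, EffectEstimate

logger = logging.getLogger(__name__)

_SQRT2 = math.sqrt(2.0)

#: Confounders of the adjusted model, retained regardless of significance.
CONFOUNDER_TERMS = {
    "age": "age",
    "sex": "C(sex)",
    "self_rated_health": "self_rated_health",
    "shift": "C(shift)",
    "medication": "medication",
    "occupation": "C(occupation)",
}

#: Pinned stratification boundaries for replication-style runs.
PINNED_AGE_EDGES = (37.0, 45.0, 51.0)
PINNED_STEPS_CUTS = (844.6, 1165.9, 1492.7)

OUTCOME_COLUMNS = ("hrr_mean", "hrr_max_1min", "ilr_z")


def ilr_two_part(p_above):
    """Isometric log-ratio balance of a two-part composition (p, 1 - p).

    Positive values mean more time at or above the cut-off.  ``p_above`` must
    lie strictly inside (0, 1); run zero replacement first.
    """
    p = np.asarray(p_above, dtype=float)
    if np.any(p <= 0.0) or np.any(p >= 1.0):
        raise ValueError("ilr requires proportions strictly inside (0, 1)")
    out = np.log(p / (1.0 - p)) / _SQRT2
    return float(out) if np.isscalar(p_above) else out


def ilr_inverse(z):
    """Inverse of :func:`ilr_two_part`: p(z) = exp(sqrt(2) z) / (1 + exp(sqrt(2) z))."""
    out = expit(_SQRT2 * np.asarray(z, dtype=float))
    return float(out) if np.isscalar(z) else out


def zero_replace(
    t_above: float, t_below: float, total: float, delta_s: float = 0.25
) -> tuple[float, float]:
    """Closure-preserving replacement of a zero part by one sample's worth of time.

    A part equal to zero is replaced by ``delta_s / total`` (one 4 Hz sample)
    and the other part reduced accordingly; when both parts are positive the
    plain proportions are returned unchanged.
    """
    if total <= 0:
        raise ValueError("total work time must be positive")
    if not math.isclose(t_above + t_below, total, rel_tol=1e-9, abs_tol=1e-6):
        raise ValueError("parts must sum to the total")
    if t_above > 0 and t_below > 0:
        return t_above / total, t_below / total
    delta = delta_s / total
    if delta >= 1.0:
        raise ValueError("replacement delta exceeds the composition")
    if t_above <= 0:
        return delta, 1.0 - delta
    return 1.0 - delta, delta


def build_analysis_table(
    workers: pd.DataFrame, summaries: pd.DataFrame, delta_s: float = 0.25
) -> pd.DataFrame:
    """Join worker covariates with workload summaries into one analysis row per worker.

    Invalid workers are dropped; the ilr coordinate is computed from the
    proportion and total valid work time with zero replacement.
    """
    df = workers.merge(summaries, on="worker_id", how="inner")
    df = df[df["valid"].astype(bool)].copy()
    if "ilr_z" not in df.columns or df["ilr_z"].isna().any():
        z = np.empty(len(df))
        for i, (p, hours) in enumerate(zip(df["prop_above_30"], df["work_time_valid_h"])):
            total = hours * 3600.0
            pa, _ = zero_replace(p * total, (1.0 - p) * total, total, delta_s=delta_s)
            z[i] = ilr_two_part(pa)
        df["ilr_z"] = z
    df["medication"] = df["medication"].astype(int)
    return df.reset_index(drop=True)


def _usable_terms(df: pd.DataFrame, exclude: Optional[str]) -> list[str]:
    terms = []
    for col, term in CONFOUNDER_TERMS.items():
        if col == exclude:
            continue
        if col not in df.columns:
            continue
        if df[col].nunique(dropna=True) < 2:
            logger.warning("dropping degenerate covariate %r (single level)", col)
            continue
        terms.append(term)
    return terms


def _estimate_from_fit(fit, term: str, model: str, outcome: str, stratum=None) -> EffectEstimate:
    ci = fit.conf_int().loc[term]
    return EffectEstimate(
        model=model,
        outcome=outcome,
        term=term,
        slope=float(fit.params[term]),
        ci_low=float(ci[0]),
        ci_high=float(ci[1]),
        p_value=float(fit.pvalues[term]),
        n=int(fit.nobs),
        stratum=stratum,
    )


def fit_model(
    df: pd.DataFrame,
    outcome: str,
    adjusted: bool = False,
    drop_covariate: Optional[str] = None,
    stratum: Optional[str] = None,
    min_rows: int = 30,
) -> EffectEstimate:
    """OLS of an outcome on fitness, optionally with the confounder set.

    Complete-case: rows missing any model variable are dropped.  Wald 95% CIs.
    """
    cols = [outcome, "vo2max_rel"]
    terms = ["vo2max_rel"]
    if adjusted:
        use = _usable_terms(df, drop_covariate)
        terms += use
        cols += [c for c, t in CONFOUNDER_TERMS.items() if t in use]
    data = df.dropna(subset=[c for c in cols if c in df.columns])
    if len(data) < min_rows:
        raise ValueError(f"need at least {min_rows} complete rows, have {len(data)}")
    formula = f"{outcome} ~ " + " + ".join(terms)
    fit = smf.ols(formula, data=data).fit()
    label = "adjusted" if adjusted else "unadjusted"
    if drop_covariate and adjusted:
        label = f"adjusted_minus_{drop_covariate}"
    return _estimate_from_fit(fit, "vo2max_rel", label, outcome, stratum)


def interaction_test(
    df: pd.DataFrame, outcome: str, moderator: str = "age"
) -> EffectEstimate:
    """Adds a mean-centred fitness x moderator product to the adjusted model."""
    data = df.copy()
    data["_vo2_c"] = data["vo2max_rel"] - data["vo2max_rel"].mean()
    data["_mod_c"] = data[moderator] - data[moderator].mean()
    terms = ["vo2max_rel"] + _usable_terms(data, None) + ["_vo2_c:_mod_c"]
    formula = f"{outcome} ~ " + " + ".join(terms)
    fit = smf.ols(formula, data=data.dropna(subset=[outcome, "vo2max_rel", moderator])).fit()
    return _estimate_from_fit(fit, "_vo2_c:_mod_c", f"interaction_{moderator}", outcome)


def _quartile_bins(x: pd.Series) -> tuple[np.ndarray, list[str]]:
    q = np.quantile(x.to_numpy(dtype=float), [0.25, 0.5, 0.75])
    edges = np.concatenate([[-np.inf], q, [np.inf]])
    labels = [
        f"<={q[0]:g}",
        f"{q[0]:g}-{q[1]:g}",
        f"{q[1]:g}-{q[2]:g}",
        f">{q[2]:g}",
    ]
    return edges, labels


def _pinned_bins(cuts: Sequence[float], integer: bool) -> tuple[np.ndarray, list[str]]:
    cuts = [float(c) for c in cuts]
    edges = np.concatenate([[-np.inf], np.asarray(cuts) + (0.5 if integer else 0.0), [np.inf]])
    if integer:
        labels = [f"<={cuts[0]:g}"]
        prev = cuts[0]
        for c in cuts[1:]:
            labels.append(f"{prev + 1:g}-{c:g}")
            prev = c
        labels.append(f">={prev + 1:g}")
    else:
        labels = [f"<{cuts[0]:g}"]
        prev = cuts[0]
        for c in cuts[1:]:
            labels.append(f"{prev:g}-{c:g}")
            prev = c
        labels.append(f">{prev:g}")
    return edges, labels


def stratum_assignments(
    df: pd.DataFrame, by: str, pinned: bool = False
) -> pd.Series:
    """Stratum label per row for one of the supported stratifications."""
    if by == "occupation":
        return df["occupation"].astype(str)
    if by == "age_quartiles":
        if pinned:
            edges, labels = _pinned_bins(PINNED_AGE_EDGES, integer=True)
        else:
            edges, labels = _quartile_bins(df["age"])
        idx = np.searchsorted(edges[1:-1], df["age"].to_numpy(dtype=float), side="right")
        return pd.Series([labels[i] for i in idx], index=df.index)
    if by == "steps_quartiles":
        if pinned:
            edges, labels = _pinned_bins(PINNED_STEPS_CUTS, integer=False)
        else:
            edges, labels = _quartile_bins(df["steps_per_hour"])
        idx = np.searchsorted(edges[1:-1], df["steps_per_hour"].to_numpy(dtype=float), side="right")
        return pd.Series([labels[i] for i in idx], index=df.index)
    raise ValueError(f"unknown stratification {by!r}")


_STRAT_DROPS = {"age_quartiles": "age", "occupation": "occupation", "steps_quartiles": None}


def stratify(
    df: pd.DataFrame,
    by: str,
    outcome: str,
    pinned: bool = False,
    n_min: int = 20,
) -> list[EffectEstimate]:
    """Adjusted fits within strata, dropping the stratifying covariate from the model.

    Strata smaller than ``n_min`` are still fit where possible but flagged
    unstable.  Stratum sizes partition the analysed sample.
    """
    labels = stratum_assignments(df, by, pinned=pinned)
    drop = _STRAT_DROPS[by]
    out: list[EffectEstimate] = []
    order = labels.drop_duplicates().tolist() if by == "occupation" else _label_order(labels)
    for label in order:
        sub = df[labels == label]
        try:
            est = fit_model(
                sub, outcome, adjusted=True, drop_covariate=drop, stratum=str(label),
                min_rows=max(8, min(n_min, len(sub))),
            )
        except ValueError:
            est = EffectEstimate(
                model=f"adjusted_minus_{drop}" if drop else "adjusted",
                outcome=outcome,
                term="vo2max_rel",
                slope=float("nan"),
                ci_low=float("nan"),
                ci_high=float("nan"),
                p_value=float("nan"),
                n=int(len(sub)),
                stratum=str(label),
                stable=False,
            )
        if len(sub) < n_min:
            est.stable = False
        out.append(est)
    return out


def _label_order(labels: pd.Series) -> list[str]:
    seen = labels.drop_duplicates().tolist()
    # keep the band construction order (labels were generated low to high)
    return sorted(seen, key=lambda s: seen.index(s))


def backtransform_delta_pct(
    df: pd.DataFrame,
    adjusted: bool = False,
    drop_covariate: Optional[str] = None,
    stratum: Optional[str] = None,
    min_rows: int = 30,
) -> CompositionEffect:
    """Fit the ilr outcome model and express its slope as an absolute work-time change.

    Delta% = 100 * [p(z_bar + b) - p(z_bar)], where z_bar is the mean fitted
    ilr coordinate (the model's prediction at covariate means) and b the
    fitness slope; CI endpoints are mapped through the same curve.
    """
    est = fit_model(df, "ilr_z", adjusted=adjusted, drop_covariate=drop_covariate,
                    stratum=stratum, min_rows=min_rows)
    z_bar = float(df["ilr_z"].dropna().mean())
    p0 = ilr_inverse(z_bar)

    def delta(b: float) -> float:
        return 100.0 * (ilr_inverse(z_bar + b) - p0)

    return CompositionEffect(
        ilr=est,
        delta_pct=delta(est.slope),
        delta_ci_low=delta(est.ci_low),
        delta_ci_high=delta(est.ci_high),
    )


def estimates_to_frame(estimates: Iterable[EffectEstimate]) -> pd.DataFrame:
    rows = []
    for e in estimates:
        rows.append(
            {
                "model": e.model,
                "outcome": e.outcome,
                "term": e.term,
                "slope": e.slope,
                "ci_low": e.ci_low,
                "ci_high": e.ci_high,
                "p_value": e.p_value,
                "n": e.n,
                "stratum": e.stratum,
                "stable": e.stable,
            }
        )
    return pd.DataFrame(rows)
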