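"""Kaplan-Meier estimation, log-rank comparison, and signature-stratified
prognostic reporting.

Estimation and testing delegate to ``lifelines``; this module supplies the
conventions used throughout the pipeline: months as the time unit, deaths
ordered before censorings at tied times (the product-limit default), a
median reported as None when the curve never reaches 0.5, and quartile
stratification where only the high and low strata enter the two-group test
(mid-stratum samples are set aside, mirroring the ~25% expected prevalence
of the driving alteration).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test

from .scoring import stratify_quantiles


@dataclass
class KMCurve:
    """A fitted product-limit curve: event-time grid, survival probability,
    and median survival (None when the curve never drops to 0.5)."""

    times: np.ndarray
    survival: np.ndarray
    median: float | None
    n: int
    n_events: int

    def at(self, t: float) -> float:
        """Survival probability at time t (right-continuous step function)."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


def _check_records(records: pd.DataFrame) -> pd.DataFrame:
    for col in ("time", "event"):
        if col not in records.columns:
            raise ValueError(f"survival records need a {col!r} column")
    if (records["time"] <= 0).any() or not np.isfinite(records["time"]).all():
        raise ValueError("times must be positive and finite")
    if not records["event"].isin([0, 1]).all():
        raise ValueError("event must be 0 (censored) or 1 (death)")
    return records


def km_estimate(records: pd.DataFrame) -> KMCurve:
    """Product-limit (Kaplan-Meier) survival estimate."""
    records = _check_records(records)
    if len(records) == 0:
        raise ValueError("need >= 1 record")
    kmf = KaplanMeierFitter()
    kmf.fit(records["time"], records["event"])
    sf = kmf.survival_function_
    median = float(kmf.median_survival_time_)
    return KMCurve(
        times=sf.index.to_numpy(dtype=float),
        survival=sf.iloc[:, 0].to_numpy(dtype=float),
        median=None if np.isinf(median) else median,
        n=len(records),
        n_events=int(records["event"].sum()),
    )


def logrank_test(records: pd.DataFrame, group_col: str = "stratum") -> tuple[float, float]:
    """Log-rank chi-square and p across >= 2 non-empty strata
    (df = groups - 1)."""
    records = _check_records(records)
    groups = records[group_col].dropna().unique()
    if len(groups) < 2:
        raise ValueError("log-rank test needs >= 2 non-empty strata")
    if records["event"].sum() == 0:
        raise ValueError("log-rank test needs >= 1 event")
    res = multivariate_logrank_test(records["time"], records[group_col], records["event"])
    return float(res.test_statistic), float(res.p_value)


def survival_report(
    scores: pd.Series,
    records: pd.DataFrame,
    hi_frac: float = 0.25,
    lo_frac: float = 0.25,
) -> dict:
    """Stratify a cohort by signature score and compare overall survival of
    the high vs low strata.

    ``records`` carries sample/time/event; samples are joined on id. The
    mid stratum is excluded from the test. Returns per-stratum KM curves,
    medians, and the two-group log-rank statistic/p.
    """
    rec = records.set_index("sample") if "sample" in records.columns else records
    shared = scores.index.intersection(rec.index)
    if len(shared) == 0:
        raise ValueError("no samples shared between scores and survival records")
    lost = 1 - len(shared) / max(len(scores), len(rec))
    if lost > 0.10:
        warnings.warn(f"join lost {lost:.0%} of samples")
    strata = stratify_quantiles(scores.loc[shared], hi_frac, lo_frac)
    joined = rec.loc[shared, ["time", "event"]].copy()
    joined["stratum"] = strata
    hl = joined[joined["stratum"].isin(["high", "low"])]
    stat, p = logrank_test(hl)
    curves = {name: km_estimate(sub) for name, sub in joined.groupby("stratum")}
    return {
        "curves": curves,
        "medians": {name: c.median for name, c in curves.items()},
        "logrank_stat": stat,
        "logrank_p": p,
        "n": {name: int((joined["stratum"] == name).sum()) for name in ("high", "mid", "low")},
    }
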