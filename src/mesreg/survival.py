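"""Expression-percentile survival stratification, Kaplan-Meier curves and
the log-rank test.

Cohorts are split by a single gene's expression: the top ``high_fraction``
of samples form the high group, the bottom ``low_fraction`` the low group,
and the middle is excluded (the 30%/30% convention). Curve estimation and
the log-rank comparison are delegated to lifelines (product-limit
estimator; classical log-rank with events preceding censorings at tied
times and no continuity correction).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank


@dataclass
class KMCurve:
    """Product-limit estimate: survival prob after each distinct event time."""

    times: np.ndarray  # distinct event times, ascending
    survival: np.ndarray  # S(t) just after each event time
    at_risk: np.ndarray  # number at risk just before each event time

    def __post_init__(self) -> None:
        assert np.all(np.diff(self.times) > 0)
        assert np.all(np.diff(self.survival) <= 1e-12)
        assert np.all((self.survival >= -1e-12) & (self.survival <= 1 + 1e-12))

    def survival_at(self, t: float) -> float:
        """S(t), with S(0) = 1 before the first event."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])

    def median(self) -> float:
        below = self.survival <= 0.5
        return float(self.times[below][0]) if below.any() else float("inf")


def stratify_by_expression(
    expr: pd.Series,
    high_fraction: float = 0.30,
    low_fraction: float = 0.30,
) -> pd.Series:
    """Label samples high / low / excluded by expression percentile.

    The top floor(high_fraction*n) samples are 'high', the bottom
    floor(low_fraction*n) 'low'; ties at a cut are resolved by sample-id
    order so the split is deterministic.
    """
    if high_fraction + low_fraction > 1.0 + 1e-12:
        raise ValueError("high_fraction + low_fraction must not exceed 1")
    n = expr.size
    if n < 4:
        raise ValueError("need >= 4 samples to stratify")
    if expr.nunique() == 1:
        warnings.warn("all expression values equal; split is by sample id only")
    ids = expr.index.to_numpy(dtype=object)
    vals = expr.to_numpy(dtype=float)
    order = np.lexsort((ids, vals))  # ascending expression, ties by sample id
    n_low = int(np.floor(low_fraction * n))
    n_high = int(np.floor(high_fraction * n))
    labels = pd.Series("excluded", index=expr.index, name="group", dtype=object)
    labels.iloc[:] = "excluded"
    labels.loc[ids[order[:n_low]]] = "low"
    if n_high > 0:
        labels.loc[ids[order[-n_high:]]] = "high"
    return labels


def km_estimate(times: np.ndarray, events: np.ndarray) -> KMCurve:
    """Kaplan-Meier product-limit curve from times and 0/1 event flags."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if times.size == 0:
        raise ValueError("no records")
    if np.any(times < 0):
        raise ValueError("negative survival time")
    if not np.isin(events, [0, 1]).all():
        raise ValueError("event flags must be 0 or 1")
    kmf = KaplanMeierFitter()
    kmf.fit(times, events)
    event_times = np.unique(times[events == 1])
    surv = kmf.survival_function_at_times(event_times).to_numpy(dtype=float)
    tbl = kmf.event_table
    at_risk = tbl.loc[event_times, "at_risk"].to_numpy(dtype=float)
    if event_times.size == 0:
        return KMCurve(np.empty(0), np.empty(0), np.empty(0))
    return KMCurve(event_times, surv, at_risk)


def logrank_test(
    times: np.ndarray, events: np.ndarray, groups: np.ndarray
) -> tuple[float, float]:
    """Two-group log-rank test; returns (chi_square, p).

    At each distinct event time the observed minus expected events in one
    group are accumulated under the hypergeometric margin model;
    chi_square = (sum O-E)^2 / (sum V) on 1 df.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    groups = np.asarray(groups)
    labels = np.unique(groups)
    if labels.size != 2:
        raise ValueError(f"log-rank needs exactly 2 groups, got {labels.tolist()}")
    for g in labels:
        if events[groups == g].sum() == 0:
            warnings.warn(f"group {g!r} has zero events")
    a, b = labels[0], labels[1]
    res = _ll_logrank(times[groups == a], times[groups == b],
                      events[groups == a], events[groups == b])
    return float(res.test_statistic), float(res.p_value)


def analyze_marker(
    expr: pd.Series,
    clinical: pd.DataFrame,
    high_fraction: float = 0.30,
    low_fraction: float = 0.30,
) -> dict:
    """Stratify by a marker gene and compare survival of high vs low.

    ``clinical`` has columns sample, time, event; only samples with both
    expression and clinical data are used. Returns the group labels, KM
    curves and the log-rank result.
    """
    clin = clinical.set_index("sample") if "sample" in clinical.columns else clinical
    shared = expr.index.intersection(clin.index)
    if len(shared) < 4:
        raise ValueError("fewer than 4 samples with both expression and survival data")
    labels = stratify_by_expression(expr.loc[shared], high_fraction, low_fraction)
    used = labels[labels != "excluded"]
    sub = clin.loc[used.index]
    chi2, p = logrank_test(sub["time"].to_numpy(), sub["event"].to_numpy(),
                           used.to_numpy(dtype=object))
    curves = {}
    for g in ("high", "low"):
        m = used == g
        curves[g] = km_estimate(sub.loc[m.to_numpy(), "time"].to_numpy(),
                                sub.loc[m.to_numpy(), "event"].to_numpy())
    return {"labels": labels, "curves": curves, "chi_square": chi2, "p": p}
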