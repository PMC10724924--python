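"""Median-split grouping, Kaplan–Meier curves, and the log-rank test.

Patients are dichotomized at the median expression of the target gene
(ties to the low group). Survival within each group is summarized by the
product-limit estimator and the groups compared with the two-group log-rank
chi-square on 1 df. Estimation is delegated to lifelines; the conventions
are the standard ones (events precede censoring at tied times).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _lifelines_logrank

from .stats import TestResult

HIGH = "high"
LOW = "low"


@dataclass
class SurvivalTable:
    """Per-sample follow-up time, event flag, and high/low group label."""

    time: pd.Series
    event: pd.Series
    group: pd.Series

    def __post_init__(self) -> None:
        self.time = pd.Series(self.time, dtype=float)
        self.event = pd.Series(self.event).astype(bool)
        self.group = pd.Series(self.group, dtype=str)
        if not (len(self.time) == len(self.event) == len(self.group)):
            raise ValueError("time/event/group lengths differ")
        if (self.time <= 0).any():
            raise ValueError("survival times must be positive")
        bad = set(self.group.unique()) - {HIGH, LOW}
        if bad:
            raise ValueError(f"unknown survival groups {sorted(bad)}")

    def restrict(self, label: str) -> "SurvivalTable":
        mask = self.group == label
        return SurvivalTable(self.time[mask], self.event[mask], self.group[mask])


@dataclass(frozen=True)
class KmCurve:
    event_times: np.ndarray  # distinct event times, ascending
    survival: np.ndarray  # S(t) just after each event time
    at_risk: np.ndarray  # n at risk just before each event time
    median_survival: float  # inf when S never reaches 0.5

    def __post_init__(self) -> None:
        if np.any(np.diff(self.survival) > 1e-12):
            raise ValueError("KM survival must be nonincreasing")


def median_split(expression: pd.Series) -> pd.Series:
    """High/low labels at the median; ties (values == median) go low."""
    expression = pd.Series(expression, dtype=float)
    if len(expression) < 2:
        raise ValueError("median split needs at least 2 samples")
    if expression.nunique() == 1:
        raise ValueError("constant expression: no median split possible")
    med = float(expression.median())
    labels = pd.Series(np.where(expression > med, HIGH, LOW), index=expression.index)
    if (labels == HIGH).sum() == 0:
        # pathological tie mass at the maximum: split strictly below median
        labels = pd.Series(
            np.where(expression >= med, HIGH, LOW), index=expression.index
        )
    return labels


def km_estimate(table: SurvivalTable) -> KmCurve:
    """Product-limit estimate for one group: S(t) = prod (1 - d_j/n_j)."""
    if len(table.time) == 0:
        raise ValueError("empty survival table")
    kmf = KaplanMeierFitter()
    kmf.fit(table.time, event_observed=table.event)
    ev = np.sort(table.time[table.event].unique())
    if ev.size == 0:
        return KmCurve(
            event_times=ev, survival=np.array([]), at_risk=np.array([], dtype=int),
            median_survival=float("inf"),
        )
    surv = kmf.survival_function_at_times(ev).to_numpy()
    # n at risk just before each event time: entered and not yet removed
    times = table.time.to_numpy()
    at_risk = np.array([(times >= t).sum() for t in ev], dtype=int)
    med = float(kmf.median_survival_time_)
    return KmCurve(event_times=ev, survival=surv, at_risk=at_risk, median_survival=med)


def logrank_test(table: SurvivalTable) -> TestResult:
    """Two-group log-rank test: chi-square (O-E)^2/V on 1 df, two-sided p."""
    high = table.group == HIGH
    low = table.group == LOW
    if high.sum() == 0 or low.sum() == 0:
        raise ValueError("log-rank needs both groups non-empty")
    if not table.event.any():
        raise ValueError("log-rank needs at least one event")
    res = _lifelines_logrank(
        table.time[high], table.time[low],
        event_observed_A=table.event[high], event_observed_B=table.event[low],
    )
    return TestResult(
        statistic=float(res.test_statistic), p_value=float(res.p_value),
        method="logrank", n=(int(high.sum()), int(low.sum())),
    )


def km_table(table: SurvivalTable) -> pd.DataFrame:
    """Per-group KM curves in one long TSV-ready frame."""
    rows = []
    for label in (HIGH, LOW):
        sub = table.restrict(label)
        if len(sub.time) == 0:
            continue
        curve = km_estimate(sub)
        for t, s, n in zip(curve.event_times, curve.survival, curve.at_risk):
            rows.append({"group": label, "time": float(t), "survival": float(s),
                         "at_risk": int(n)})
    return pd.DataFrame(rows, columns=["group", "time", "survival", "at_risk"])
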