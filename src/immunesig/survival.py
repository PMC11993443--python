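"""Kaplan–Meier estimation and the log-rank test for post-NAC prognosis.

Distant recurrence-free survival is summarised per subtype group with the
product-limit estimator (events before censorings at tied times, the
standard convention) and groups are compared with the log-rank test.
Median follow-up is computed by reverse Kaplan–Meier (censoring treated as
the event).  Estimation is delegated to lifelines.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test

__all__ = ["KMCurve", "km_estimate", "logrank", "median_followup"]


@dataclasses.dataclass
class KMCurve:
    """One group's product-limit curve with at-risk counts."""

    group: str
    table: pd.DataFrame  # columns: time, survival, at_risk

    def __post_init__(self) -> None:
        surv = self.table["survival"].to_numpy()
        if (np.diff(surv) > 1e-12).any():
            raise ValueError("survival curve must be nonincreasing")

    def survival_at(self, t: float) -> float:
        earlier = self.table[self.table["time"] <= t]
        return float(earlier["survival"].iloc[-1]) if len(earlier) else 1.0


def _validate(times, events) -> tuple[np.ndarray, np.ndarray]:
    times = np.asarray(times, dtype=float)
    events = np.asarray(events).astype(bool)
    if times.size != events.size:
        raise ValueError("times and events must be paired")
    if (times < 0).any():
        raise ValueError("negative survival times")
    return times, events


def km_estimate(times, events, groups=None) -> dict[str, KMCurve]:
    """Kaplan–Meier curve per group (single group 'all' when groups is None)."""
    times, events = _validate(times, events)
    groups = (
        np.asarray(["all"] * times.size) if groups is None else np.asarray(groups).astype(str)
    )
    curves: dict[str, KMCurve] = {}
    for label in pd.unique(groups):
        mask = groups == label
        fitter = KaplanMeierFitter()
        fitter.fit(times[mask], events[mask])
        timeline = fitter.survival_function_.index.to_numpy(dtype=float)
        surv = fitter.survival_function_.iloc[:, 0].to_numpy(dtype=float)
        at_risk = (
            fitter.event_table["at_risk"].reindex(fitter.survival_function_.index).to_numpy()
        )
        curves[str(label)] = KMCurve(
            group=str(label),
            table=pd.DataFrame({"time": timeline, "survival": surv, "at_risk": at_risk}),
        )
    return curves


def logrank(times, events, groups) -> tuple[float, float]:
    """Log-rank chi-square and p across >=2 groups (df = groups − 1)."""
    times, events = _validate(times, events)
    groups = np.asarray(groups).astype(str)
    if pd.unique(groups).size < 2:
        raise ValueError("log-rank needs >=2 groups")
    if not events.any():
        raise ValueError("log-rank needs >=1 event")
    result = multivariate_logrank_test(times, groups, events)
    return float(result.test_statistic), float(result.p_value)


def median_followup(times, events) -> float:
    """Median follow-up by reverse Kaplan–Meier (censorings as events)."""
    times, events = _validate(times, events)
    fitter = KaplanMeierFitter()
    fitter.fit(times, ~events)
    return float(fitter.median_survival_time_)
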