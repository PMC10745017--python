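"""Time-to-respiratory-support analysis: Kaplan-Meier curves and log-rank test.

Event-free "survival" here is remaining free of respiratory support by time
t (hours from the record's time origin).  The product-limit estimator and
the Mantel-Cox log-rank statistic are computed through lifelines; this
module fixes the conventions the pipeline relies on: events precede
censorings at tied times, events recorded at time 0 enter the first risk
set, and no continuity correction is applied to the log-rank statistic.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank

from .scoring import ValidationError

__all__ = [
    "TimeToEvent",
    "KMEstimate",
    "LogRankResult",
    "km_fit",
    "km_survival_at",
    "logrank_test",
]


@dataclass(frozen=True)
class TimeToEvent:
    """One observation: hours to support initiation, or right-censoring time."""

    time_h: float
    event: bool  # True = support initiated at time_h, False = censored

    def __post_init__(self) -> None:
        if not np.isfinite(self.time_h) or self.time_h < 0:
            raise ValidationError(f"time_h must be finite and >= 0, got {self.time_h!r}")


@dataclass(frozen=True)
class KMEstimate:
    """Product-limit estimate over the distinct event times.

    ``survival[i]`` is S(event_times[i]) = prod_{t_j <= t_i} (1 - d_j/n_j);
    ``at_risk`` and ``n_events`` are the risk-set size and event count at
    each event time.  ``n`` is the sample size behind the curve.
    """

    event_times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    n_events: np.ndarray
    n: int


@dataclass(frozen=True)
class LogRankResult:
    chi_square: float
    df: int
    p_value: float


def _to_arrays(records: Iterable[TimeToEvent]) -> tuple[np.ndarray, np.ndarray]:
    recs = list(records)
    if not recs:
        raise ValidationError("at least one observation is required")
    times = np.array([r.time_h for r in recs], dtype=float)
    events = np.array([r.event for r in recs], dtype=bool)
    return times, events


def km_fit(records: Sequence[TimeToEvent]) -> KMEstimate:
    """Kaplan-Meier product-limit fit of event-free survival.

    Censored observations tied with an event time remain at risk for that
    event (the standard events-before-censorings convention).
    """
    times, events = _to_arrays(records)
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    table = kmf.event_table
    mask = table["observed"].to_numpy() > 0
    event_times = table.index.to_numpy(dtype=float)[mask]
    n_events = table["observed"].to_numpy(dtype=int)[mask]
    at_risk = table["at_risk"].to_numpy(dtype=int)[mask]
    surv = np.array(
        [float(kmf.survival_function_at_times(t).iloc[0]) for t in event_times]
    )
    return KMEstimate(
        event_times=event_times,
        survival=surv,
        at_risk=at_risk,
        n_events=n_events,
        n=len(times),
    )


def km_survival_at(est: KMEstimate, t: float) -> float:
    """Right-continuous step-function evaluation of S(t)."""
    if t < 0:
        raise ValidationError(f"t must be >= 0, got {t}")
    idx = np.searchsorted(est.event_times, t, side="right") - 1
    return 1.0 if idx < 0 else float(est.survival[idx])


def logrank_test(
    group_a: Sequence[TimeToEvent], group_b: Sequence[TimeToEvent]
) -> LogRankResult:
    """Two-sample Mantel-Cox log-rank test (df = 1, no continuity correction)."""
    times_a, events_a = _to_arrays(group_a)
    times_b, events_b = _to_arrays(group_b)
    if events_a.sum() + events_b.sum() == 0:
        raise ValidationError("log-rank statistic undefined with zero events overall")
    res = _ll_logrank(times_a, times_b, event_observed_A=events_a, event_observed_B=events_b)
    return LogRankResult(
        chi_square=float(res.test_statistic), df=1, p_value=float(res.p_value)
    )
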