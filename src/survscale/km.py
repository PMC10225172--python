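"""Kaplan-Meier product-limit estimation with Greenwood variance.

The estimator is implemented from scratch (vectorised over distinct event
times) because the multiplicative counterfactual model downstream operates
directly on the fitted step function and its variance; external survival
packages serve only as cross-checks in the test suite.

Confidence intervals use the complementary log-log transform, which keeps the
bounds inside [0, 1]:

    ci = S ** exp( +/- z * sqrt(var) / (S * ln S) )

At horizons past the last observed time the step function is carried forward
(the last Kaplan-Meier value), with an :class:`ExtrapolationWarning` — with a
median potential follow-up of ~6 years a 15-year landmark necessarily
extrapolates, and silently erroring there would make landmark reporting
impossible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "EventRecord",
    "SurvivalCurve",
    "ExtrapolationWarning",
    "km_fit",
    "survival_at",
    "risk_at",
    "records_from_frame",
]


class ExtrapolationWarning(UserWarning):
    """Landmark evaluated beyond the largest observed time."""


@dataclass(frozen=True)
class EventRecord:
    """One subject's follow-up for one endpoint."""

    time: float
    event: int

    def __post_init__(self) -> None:
        if not np.isfinite(self.time) or self.time < 0:
            raise ValueError("time must be finite and >= 0")
        if self.event not in (0, 1):
            raise ValueError("event must be 0 or 1")


@dataclass(frozen=True)
class SurvivalCurve:
    """Product-limit estimate as a right-continuous step function.

    All arrays are aligned on the distinct event times (times with >= 1
    event).  ``survival[i]`` is S(t) just after ``event_times[i]``;
    ``variance`` is the Greenwood estimate of Var S(t); ``ci_low``/``ci_high``
    are pointwise bounds at ``ci_level``.  ``max_observed_time`` is the
    largest time in the data, event or censored.
    """

    event_times: np.ndarray
    n_risk: np.ndarray
    n_event: np.ndarray
    survival: np.ndarray
    variance: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    n_total: int
    max_observed_time: float
    ci_level: float = 0.95

    def survival_at(self, t) -> np.ndarray | float:
        return survival_at(self, t)

    def risk_at(self, t) -> np.ndarray | float:
        return risk_at(self, t)

    def to_frame(self) -> pd.DataFrame:
        """Survival table: time, n_risk, n_event, survival, variance, CI."""
        return pd.DataFrame(
            {
                "time": self.event_times,
                "n_risk": self.n_risk,
                "n_event": self.n_event,
                "survival": self.survival,
                "variance": self.variance,
                "ci_low": self.ci_low,
                "ci_high": self.ci_high,
            }
        )


def _as_time_event(records) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(records, pd.DataFrame):
        return records["time"].to_numpy(float), records["event"].to_numpy(int)
    if isinstance(records, tuple) and len(records) == 2 and np.ndim(records[0]) == 1:
        return np.asarray(records[0], float), np.asarray(records[1], int)
    times, events = [], []
    for r in records:
        if isinstance(r, EventRecord):
            times.append(r.time)
            events.append(r.event)
        else:
            t, e = r
            times.append(float(t))
            events.append(int(e))
    return np.asarray(times, float), np.asarray(events, int)


def km_fit(records, ci_level: float = 0.95) -> SurvivalCurve:
    """Fit the Kaplan-Meier product-limit estimator.

    Parameters
    ----------
    records
        Iterable of :class:`EventRecord` (or ``(time, event)`` pairs), a
        DataFrame with ``time``/``event`` columns, or a ``(times, events)``
        pair of arrays.
    ci_level
        Pointwise confidence level in (0, 1).

    Notes
    -----
    At tied times, events are processed before censorings: a subject censored
    at t is still at risk for an event at t.  S(t) = prod_{t_i <= t}
    (1 - d_i/n_i); Greenwood variance S(t)^2 * sum d_i / (n_i (n_i - d_i)).
    """
    times, events = _as_time_event(records)
    if times.size == 0:
        raise ValueError("need at least one record")
    if not 0.0 < ci_level < 1.0:
        raise ValueError("ci_level must be in (0, 1)")
    if np.any(times < 0) or not np.all(np.isfinite(times)):
        raise ValueError("times must be finite and >= 0")
    if not np.isin(events, (0, 1)).all():
        raise ValueError("event flags must be 0 or 1")

    n = times.size
    order = np.argsort(times, kind="stable")
    t_sorted = times[order]
    e_sorted = events[order]

    uniq, first_idx = np.unique(t_sorted, return_index=True)
    # events per distinct time; at risk = subjects with time >= t (ties of
    # censored subjects still count, i.e. events before censorings)
    d = np.add.reduceat(e_sorted, first_idx)
    at_risk = n - first_idx
    keep = d > 0
    event_times = uniq[keep]
    d = d[keep]
    n_risk = at_risk[keep]

    frac = 1.0 - d / n_risk
    surv = np.cumprod(frac)
    with np.errstate(divide="ignore", invalid="ignore"):
        gw_terms = np.where(n_risk > d, d / (n_risk * (n_risk - d)), np.inf)
    cum_gw = np.cumsum(gw_terms)
    var = np.where(surv > 0, surv**2 * np.where(np.isfinite(cum_gw), cum_gw, 0.0), 0.0)
    # S hits 0 when the last at-risk subject dies; variance is 0 there (the
    # Greenwood sum diverges but S^2 -> 0 faster in the product-limit limit)

    ci_low, ci_high = _cloglog_ci(surv, var, ci_level)
    return SurvivalCurve(
        event_times=event_times,
        n_risk=n_risk,
        n_event=d,
        survival=surv,
        variance=var,
        ci_low=ci_low,
        ci_high=ci_high,
        n_total=n,
        max_observed_time=float(t_sorted[-1]),
        ci_level=ci_level,
    )


def _cloglog_ci(
    surv: np.ndarray, var: np.ndarray, ci_level: float
) -> tuple[np.ndarray, np.ndarray]:
    z = stats.norm.ppf(0.5 + ci_level / 2.0)
    low = np.zeros_like(surv)
    high = np.ones_like(surv)
    interior = (surv > 0.0) & (surv < 1.0)
    s = surv[interior]
    se_cll = np.sqrt(var[interior]) / (s * np.abs(np.log(s)))
    low[interior] = s ** np.exp(z * se_cll)
    high[interior] = s ** np.exp(-z * se_cll)
    # degenerate points: S=1 (no events yet) or S=0 (all dead)
    low[surv == 1.0] = 1.0
    high[surv == 0.0] = 0.0
    return low, high


def survival_at(curve: SurvivalCurve, t) -> np.ndarray | float:
    """Right-continuous step evaluation of S at time(s) ``t``.

    Returns 1 before the first event time and the last value beyond the last
    event time; warns with :class:`ExtrapolationWarning` when ``t`` exceeds
    the largest observed (event or censoring) time.
    """
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("t must be >= 0")
    if np.any(t_arr > curve.max_observed_time):
        warnings.warn(
            f"evaluating survival beyond the last observed time "
            f"({curve.max_observed_time:g} y); carrying the last value forward",
            ExtrapolationWarning,
            stacklevel=2,
        )
    step = np.concatenate([[1.0], curve.survival])
    idx = np.searchsorted(curve.event_times, t_arr, side="right")
    out = step[idx]
    return float(out) if t_arr.ndim == 0 else out


def risk_at(curve: SurvivalCurve, t) -> np.ndarray | float:
    """Cumulative risk 1 - S(t)."""
    s = survival_at(curve, t)
    return 1.0 - s


def records_from_frame(df: pd.DataFrame, endpoint: str) -> pd.DataFrame:
    """Select one endpoint from a cohort table into time/event columns."""
    tcol, ecol = f"{endpoint}_time", f"{endpoint}_event"
    if tcol not in df.columns or ecol not in df.columns:
        raise ValueError(f"cohort table has no columns for endpoint {endpoint!r}")
    return pd.DataFrame({"time": df[tcol].astype(float), "event": df[ecol].astype(int)})
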