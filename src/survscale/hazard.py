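"""Piecewise-exponential hazard model.

A piecewise-constant hazard is the simplest generative model that passes
*exactly* through a set of landmark survival probabilities: on each interval
between landmarks the hazard is constant, so the log-survival is piecewise
linear and the calibration is a closed-form inversion.  This makes the model
the natural stand-in for a cohort whose survival is only reported at a few
horizons (here 5, 10 and 15 years).

The hazard on the last interval extends indefinitely, so event times beyond
the last knot remain well defined.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np

__all__ = ["PiecewiseHazard", "calibrate_piecewise_hazard", "sample_event_times"]


@dataclass(frozen=True)
class PiecewiseHazard:
    """Piecewise-constant hazard over knot intervals.

    Parameters
    ----------
    knots
        Strictly increasing interval start times in years; ``knots[0]`` must
        be 0.  Interval ``j`` is ``[knots[j], knots[j+1])``; the last interval
        extends to ``+inf``.
    rates
        Hazard per year on each interval, one per knot; all non-negative.
    """

    knots: tuple[float, ...]
    rates: tuple[float, ...]

    def __post_init__(self) -> None:
        knots = tuple(float(k) for k in self.knots)
        rates = tuple(float(r) for r in self.rates)
        if len(knots) == 0 or len(knots) != len(rates):
            raise ValueError("need len(rates) == len(knots) >= 1")
        if knots[0] != 0.0:
            raise ValueError("knots must start at 0")
        if any(b <= a for a, b in zip(knots, knots[1:])):
            raise ValueError("knots must be strictly increasing")
        if any(r < 0 or not math.isfinite(r) for r in rates):
            raise ValueError("rates must be finite and >= 0")
        object.__setattr__(self, "knots", knots)
        object.__setattr__(self, "rates", rates)

    def _knot_cumhaz(self) -> np.ndarray:
        """Cumulative hazard at each knot (0 at t=0)."""
        k = np.asarray(self.knots)
        r = np.asarray(self.rates)
        return np.concatenate([[0.0], np.cumsum(r[:-1] * np.diff(k))])

    def cumulative_hazard(self, t) -> np.ndarray | float:
        """H(t) = integral of the hazard from 0 to t (vectorised)."""
        t_arr = np.asarray(t, dtype=float)
        if np.any(t_arr < 0):
            raise ValueError("time must be >= 0")
        k = np.asarray(self.knots)
        r = np.asarray(self.rates)
        cum = self._knot_cumhaz()
        idx = np.searchsorted(k, t_arr, side="right") - 1
        out = cum[idx] + r[idx] * (t_arr - k[idx])
        return out if t_arr.ndim else float(out)

    def survival(self, t) -> np.ndarray | float:
        """S(t) = exp(-H(t))."""
        return np.exp(np.negative(self.cumulative_hazard(t)))


def calibrate_piecewise_hazard(
    landmark_survival: Mapping[float, float],
) -> PiecewiseHazard:
    """Invert landmark survival probabilities into a piecewise hazard.

    Given survival probabilities ``S(t_j)`` at horizons ``t_1 < ... < t_m``
    (with the implicit ``S(0) = 1``), returns the piecewise-constant hazard
    whose survival function passes exactly through every landmark:

        lambda_j = ln(S(t_{j-1}) / S(t_j)) / (t_j - t_{j-1})

    The last interval's rate is carried beyond the final landmark.

    Raises
    ------
    ValueError
        If any survival value is not in (0, 1], any horizon is not positive,
        or the values increase over time.
    """
    if not landmark_survival:
        raise ValueError("need at least one landmark")
    times = sorted(float(t) for t in landmark_survival)
    if times[0] <= 0:
        raise ValueError("landmark times must be > 0")
    surv = [float(landmark_survival[t]) for t in times]
    prev_t, prev_s = 0.0, 1.0
    rates: list[float] = []
    for t, s in zip(times, surv):
        if not 0.0 < s <= 1.0:
            raise ValueError(f"survival at t={t} must be in (0, 1], got {s}")
        if s > prev_s:
            raise ValueError("landmark survival must be non-increasing in time")
        rates.append(math.log(prev_s / s) / (t - prev_t))
        prev_t, prev_s = t, s
    # extend the final interval's rate past the last landmark
    rates.append(rates[-1])
    return PiecewiseHazard(knots=(0.0, *times), rates=tuple(rates))


def sample_event_times(
    hazard: PiecewiseHazard, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw ``n`` i.i.d. event times by inverse-transform sampling.

    Draws a unit-exponential deviate E and solves H(T) = E for T, exploiting
    the piecewise-linear cumulative hazard.  Draws whose target exceeds the
    total attainable cumulative hazard (possible only when the terminal rate
    is 0) come back as ``+inf``; with all rates 0 every draw is ``+inf``.
    """
    if n <= 0:
        raise ValueError("n must be > 0")
    e = rng.exponential(size=n)
    k = np.asarray(hazard.knots)
    r = np.asarray(hazard.rates)
    cum = hazard._knot_cumhaz()
    # side='right' skips zero-rate intervals, where cum is flat
    idx = np.clip(np.searchsorted(cum, e, side="right") - 1, 0, len(k) - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = k[idx] + (e - cum[idx]) / r[idx]
    t[(r[idx] == 0.0) & (e > cum[idx])] = np.inf
    # zero-rate interval with e exactly on its cumhaz: event at interval start
    t[(r[idx] == 0.0) & (e <= cum[idx])] = k[idx][(r[idx] == 0.0) & (e <= cum[idx])]
    return t
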