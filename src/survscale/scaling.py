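"""Counterfactual risk-ratio scaling, excess risk and number needed to harm.

The model: the hypothetical (deferred-treatment) cohort's cumulative risk at
every horizon is a fixed multiple k of the observed cohort's cumulative risk,

    risk_AS(t) = k * risk_RP(t),        k >= 1,

so the excess absolute risk is (k - 1) * x for baseline risk x, and the
number needed to harm is its reciprocal.  This operates on the *risk* scale;
it is deliberately not proportional-hazards scaling (S^k), which at a risk
doubling would give 1 - S^2 < 2 * (1 - S).  A hazard-ratio variant is exposed
behind an explicit flag for sensitivity analysis only.

Grid evaluation is carried out in decimal arithmetic so that reported
percentages round exactly (round-half-up) without binary-float artifacts at
midpoints like 0.105.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Sequence

import numpy as np

from .km import SurvivalCurve

__all__ = [
    "Scenario",
    "RiskResult",
    "excess_risk",
    "scaled_risk",
    "nnh",
    "scale_survival_curve",
    "evaluate_grid",
    "round_half_up",
]


def _to_decimal(x) -> Decimal:
    """Exact conversion: strings/Decimals verbatim, floats via shortest repr."""
    if isinstance(x, Decimal):
        return x
    if isinstance(x, float):
        return Decimal(repr(x))
    return Decimal(str(x))


def round_half_up(value, ndigits: int = 2) -> Decimal:
    """Decimal round-half-up (0.105 -> 0.11 at 2 digits, 134.5 -> 135 at 0)."""
    q = Decimal(1).scaleb(-ndigits)
    return _to_decimal(value).quantize(q, rounding=ROUND_HALF_UP)


@dataclass(frozen=True)
class Scenario:
    """One cell of the scenario grid: risk multiplier k at horizon t years."""

    multiplier: float
    horizon: float

    def __post_init__(self) -> None:
        if self.multiplier < 1:
            raise ValueError("multiplier must be >= 1 (the model describes harm)")
        if self.horizon <= 0:
            raise ValueError("horizon must be > 0")


def excess_risk(x: float, k: float) -> float:
    """Excess absolute risk (k - 1) * x of the scaled cohort over baseline."""
    _check_risk_args(x, k)
    return (k - 1.0) * x


def scaled_risk(x: float, k: float) -> float:
    """Total risk k * x in the scaled cohort."""
    _check_risk_args(x, k)
    return k * x


def _check_risk_args(x: float, k: float) -> None:
    if not 0.0 <= x <= 1.0:
        raise ValueError(f"baseline risk must be a probability, got {x}")
    if k < 1.0:
        raise ValueError("multiplier must be >= 1 (the model describes harm)")
    if k * x > 1.0 + 1e-12:
        raise ValueError(f"scaled risk k*x = {k * x:.4g} is not a probability")


def nnh(excess: float) -> float:
    """Number needed to harm: 1 / excess risk, unrounded.

    The reporting layer rounds half-up to the nearest integer.  Zero or
    negative excess has no finite NNH and is rejected.
    """
    if excess <= 0.0:
        raise ValueError("NNH is undefined for excess risk <= 0")
    return 1.0 / excess


def scale_survival_curve(
    curve: SurvivalCurve, k: float, model: str = "risk-ratio"
) -> SurvivalCurve:
    """Scale a fitted survival curve to the counterfactual cohort.

    ``model="risk-ratio"`` (the default and the study model) maps pointwise
    S'(t) = 1 - k * (1 - S(t)) on the same event-time grid, with variance
    k^2 * Var S (delta method on the risk scale) and confidence bounds mapped
    the same way (clipped to [0, 1]).

    ``model="hazard-ratio"`` applies proportional-hazards scaling S^k with
    delta-method variance (k S^{k-1})^2 Var S.  This is *not* the study
    model; it is provided for sensitivity analysis.
    """
    if k < 1.0:
        raise ValueError("multiplier must be >= 1")
    if model == "risk-ratio":
        max_risk = 1.0 - float(np.min(curve.survival, initial=1.0))
        if k * max_risk > 1.0 + 1e-12:
            raise ValueError(
                f"k * max risk = {k * max_risk:.4g} exceeds 1; curve cannot be "
                "scaled on the risk scale"
            )
        surv = 1.0 - k * (1.0 - curve.survival)
        var = (k**2) * curve.variance
        lo = np.clip(1.0 - k * (1.0 - curve.ci_low), 0.0, 1.0)
        hi = np.clip(1.0 - k * (1.0 - curve.ci_high), 0.0, 1.0)
    elif model == "hazard-ratio":
        surv = curve.survival**k
        var = (k * curve.survival ** (k - 1.0)) ** 2 * curve.variance
        lo = curve.ci_low**k
        hi = curve.ci_high**k
    else:
        raise ValueError("model must be 'risk-ratio' or 'hazard-ratio'")
    return dataclasses.replace(
        curve, survival=surv, variance=var, ci_low=lo, ci_high=hi
    )


@dataclass(frozen=True)
class RiskResult:
    """One scenario-grid cell, held in exact decimal arithmetic.

    ``baseline``, ``scaled`` and ``excess`` are probabilities (Decimal);
    ``nnh`` is the unrounded reciprocal of the excess (Decimal, or None when
    the excess is zero — an infinite NNH cell).
    """

    scenario: Scenario
    baseline: Decimal
    scaled: Decimal
    excess: Decimal
    nnh: Decimal | None

    def excess_pct(self, ndigits: int = 2) -> Decimal:
        return round_half_up(self.excess * 100, ndigits)

    def scaled_pct(self, ndigits: int = 2) -> Decimal:
        return round_half_up(self.scaled * 100, ndigits)

    def baseline_pct(self, ndigits: int = 2) -> Decimal:
        return round_half_up(self.baseline * 100, ndigits)

    def nnh_rounded(self, ndigits: int = 0) -> Decimal | None:
        return None if self.nnh is None else round_half_up(self.nnh, ndigits)


def evaluate_grid(
    baselines: Mapping[float, object],
    multipliers: Sequence[object],
    *,
    percent: bool = True,
) -> list[RiskResult]:
    """Evaluate the excess-risk / NNH grid over horizons x multipliers.

    Parameters
    ----------
    baselines
        Map horizon (years) -> baseline risk x.  Values may be str, Decimal
        or float; strings/Decimals are taken verbatim so printed table values
        round exactly.
    multipliers
        Risk multipliers k >= 1 (str/Decimal/float).
    percent
        If True (default) baselines are on the percent scale (``"2.17"``
        means 2.17%); if False they are probabilities.

    Returns one :class:`RiskResult` per (horizon, multiplier) pair, in
    horizon-major order.
    """
    ks = [_to_decimal(k) for k in multipliers]
    if any(k < 1 for k in ks):
        raise ValueError("multipliers must be >= 1")
    results: list[RiskResult] = []
    for horizon in sorted(baselines):
        x = _to_decimal(baselines[horizon])
        if percent:
            x = x / 100
        if not 0 <= x <= 1:
            raise ValueError(f"baseline risk at t={horizon} is not a probability")
        for k in ks:
            if k * x > 1:
                raise ValueError(
                    f"scaled risk {k}*{x} exceeds 1 at horizon {horizon}"
                )
            excess = (k - 1) * x
            results.append(
                RiskResult(
                    scenario=Scenario(multiplier=float(k), horizon=float(horizon)),
                    baseline=x,
                    scaled=k * x,
                    excess=excess,
                    nnh=None if excess == 0 else Decimal(1) / excess,
                )
            )
    return results
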