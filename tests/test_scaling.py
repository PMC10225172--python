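"""Risk-ratio scaling, excess risk, NNH and the exact decimal grid."""

from decimal import Decimal

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from survscale import (
    Scenario,
    evaluate_grid,
    excess_risk,
    km_fit,
    nnh,
    risk_at,
    round_half_up,
    scale_survival_curve,
    scaled_risk,
    survival_at,
)

# published scenario grid: baseline risk x (percent) by horizon, and the
# rounded excess-risk / NNH cells it implies
BASELINES_PCT = {5.0: "0.14", 10.0: "0.99", 15.0: "2.17"}
MULTIPLIERS = ["1.25", "1.5", "1.75", "2.0"]
EXPECTED_EXCESS = {
    5.0: ["0.04", "0.07", "0.11", "0.14"],
    10.0: ["0.25", "0.50", "0.74", "0.99"],
    15.0: ["0.54", "1.09", "1.63", "2.17"],
}
EXPECTED_NNH = {
    5.0: [2857, 1429, 952, 714],
    10.0: [404, 202, 135, 101],  # 1.75x computes to 135 (1/0.007425)
    15.0: [184, 92, 61, 46],
}


class TestPointOperations:
    @pytest.mark.parametrize(
        "x, k, expected",
        [
            (0.0217, 1.25, 0.005425),
            (0.0099, 2.0, 0.0099),
            (0.5, 1.0, 0.0),
        ],
    )
    def test_excess_risk(self, x, k, expected):
        assert excess_risk(x, k) == pytest.approx(expected, abs=1e-15)

    @pytest.mark.parametrize(
        "x, k, expected",
        [
            (0.0099, 2.0, 0.0198),
            (0.0, 3.0, 0.0),
            (0.0217, 2.0, 0.0434),
        ],
    )
    def test_scaled_risk(self, x, k, expected):
        assert scaled_risk(x, k) == pytest.approx(expected, abs=1e-15)
        assert scaled_risk(x, k) == pytest.approx(
            x + excess_risk(x, k), abs=1e-15
        )

    @pytest.mark.parametrize(
        "excess, expected_rounded",
        [(0.005425, 184), (0.0217, 46), (0.5, 2)],
    )
    def test_nnh_reciprocal(self, excess, expected_rounded):
        assert nnh(excess) == pytest.approx(1 / excess)
        assert int(round_half_up(nnh(excess), 0)) == expected_rounded

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            excess_risk(0.6, 2.0)  # scaled risk above 1
        with pytest.raises(ValueError):
            excess_risk(0.1, 0.9)  # benefit is out of model scope
        with pytest.raises(ValueError):
            scaled_risk(1.5, 1.0)  # not a probability
        with pytest.raises(ValueError):
            nnh(0.0)
        with pytest.raises(ValueError):
            nnh(-0.1)
        with pytest.raises(ValueError):
            Scenario(multiplier=0.5, horizon=10)
        with pytest.raises(ValueError):
            Scenario(multiplier=1.5, horizon=0)

    @given(
        st.floats(min_value=1e-6, max_value=0.4),
        st.floats(min_value=1.0, max_value=2.0, exclude_min=True),
        st.floats(min_value=1.0, max_value=2.0, exclude_min=True),
    )
    def test_monotone_in_multiplier(self, x, k1, k2):
        lo, hi = sorted([k1, k2])
        if lo == hi:
            return
        assert excess_risk(x, lo) < excess_risk(x, hi)
        assert nnh(excess_risk(x, lo)) > nnh(excess_risk(x, hi))


class TestRounding:
    @pytest.mark.parametrize(
        "value, ndigits, expected",
        [
            ("0.105", 2, "0.11"),  # half-up at the midpoint
            ("1.085", 2, "1.09"),
            ("134.5", 0, "135"),
            (Decimal("0.2475"), 2, "0.25"),
            (184.333, 0, "184"),
        ],
    )
    def test_half_up(self, value, ndigits, expected):
        assert str(round_half_up(value, ndigits)) == expected


class TestGrid:
    def test_published_grid_reproduced(self):
        results = evaluate_grid(BASELINES_PCT, MULTIPLIERS)
        assert len(results) == 12
        by_cell = {
            (r.scenario.horizon, r.scenario.multiplier): r for r in results
        }
        for h, cells in EXPECTED_EXCESS.items():
            for k, exp_excess, exp_nnh in zip(
                (1.25, 1.5, 1.75, 2.0), cells, EXPECTED_NNH[h]
            ):
                r = by_cell[(h, k)]
                assert str(r.excess_pct(2)) == exp_excess
                assert int(r.nnh_rounded()) == exp_nnh
                # additivity holds exactly in decimal arithmetic
                assert r.scaled == r.baseline + r.excess
                assert r.nnh * r.excess == pytest.approx(Decimal(1))

    def test_unit_multiplier_flags_infinite_nnh(self):
        (r,) = evaluate_grid({10.0: "0.99"}, ["1"])
        assert r.excess == 0
        assert r.nnh is None

    def test_grid_validation(self):
        with pytest.raises(ValueError):
            evaluate_grid({10.0: "60"}, ["2.0"])  # scaled risk 120%
        with pytest.raises(ValueError):
            evaluate_grid({10.0: "0.99"}, ["0.5"])


class TestCurveScaling:
    @pytest.fixture()
    def curve(self):
        # low cumulative risk (rare event, heavy censoring) so that the
        # 1.25-2x multipliers keep the scaled risk inside [0, 1]
        rng = np.random.default_rng(11)
        event_t = rng.exponential(100, size=400)
        censor_t = rng.uniform(5, 20, size=400)
        times = np.minimum(event_t, censor_t)
        events = (event_t <= censor_t).astype(int)
        return km_fit((times, events))

    def test_identity_multiplier(self, curve):
        out = scale_survival_curve(curve, 1.0)
        np.testing.assert_allclose(out.survival, curve.survival, atol=0)
        np.testing.assert_allclose(out.variance, curve.variance, atol=0)

    def test_pointwise_risk_doubling(self):
        curve = km_fit([(15, 1)] * 22 + [(16, 0)] * 978)  # S(15) = 0.978
        assert survival_at(curve, 15) == pytest.approx(0.978, abs=1e-12)
        scaled = scale_survival_curve(curve, 2.0)
        assert survival_at(scaled, 15) == pytest.approx(0.9560, abs=1e-12)

    def test_consistent_with_point_arithmetic(self, curve):
        k = 1.75
        scaled = scale_survival_curve(curve, k)
        for t in [1.0, 5.0, 10.0]:
            assert risk_at(scaled, t) == pytest.approx(
                scaled_risk(risk_at(curve, t), k), abs=1e-12
            )

    def test_variance_scales_quadratically(self, curve):
        out = scale_survival_curve(curve, 2.0)
        np.testing.assert_allclose(out.variance, 4.0 * curve.variance, atol=0)

    def test_invariants_preserved(self, curve):
        out = scale_survival_curve(curve, 1.5)
        assert np.all(np.diff(out.survival) <= 1e-15)
        assert np.all((out.ci_low >= 0) & (out.ci_high <= 1))
        assert np.all(out.ci_low <= out.survival + 1e-12)
        assert np.all(out.survival <= out.ci_high + 1e-12)

    def test_domain_error_when_risk_leaves_unit_interval(self):
        # a curve reaching 60% risk cannot be doubled on the risk scale
        risky = km_fit([(1, 1), (2, 1), (3, 1), (4, 0), (5, 0)])
        with pytest.raises(ValueError):
            scale_survival_curve(risky, 2.0)

    def test_hazard_ratio_variant_is_weaker(self):
        """Proportional-hazards scaling S^k yields strictly less excess than
        risk-scale doubling (1 - S^2 < 2(1 - S) for S in (0, 1))."""
        curve = km_fit([(15, 1)] * 22 + [(16, 0)] * 978)
        risk_scale = scale_survival_curve(curve, 2.0, model="risk-ratio")
        haz_scale = scale_survival_curve(curve, 2.0, model="hazard-ratio")
        x = risk_at(curve, 15)
        assert risk_at(risk_scale, 15) - x == pytest.approx(x, abs=1e-12)
        assert risk_at(haz_scale, 15) - x < x
        with pytest.raises(ValueError):
            scale_survival_curve(curve, 2.0, model="nope")

    def test_degenerate_flat_curve(self):
        curve = km_fit([(5, 0)] * 10)  # no events: S identically 1
        out = scale_survival_curve(curve, 2.0)
        assert survival_at(out, 4.0) == 1.0
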