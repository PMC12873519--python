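"""Stacked-conduit Poiseuille model and resistance-balancing tip law."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from leafxylem.hydraulics import (
    ConduitProfile,
    TipWideningLaw,
    analytic_cumulative_resistance,
    balance_tip_diameter,
    conductance_ratio,
    cumulative_resistance,
    diameter_at,
    implied_exponent,
    segment_resistance,
    tip_diameter_at_height,
)


class TestDiameterAt:
    def test_constant_tube_when_b_zero(self):
        p = ConduitProfile(d_ref=12.0, x_ref=5.0, b=0.0)
        assert diameter_at(p, 1.0) == 12.0
        assert diameter_at(p, 500.0) == 12.0

    def test_exact_doubling_at_32mm(self):
        # 32**0.2 == 2 exactly
        p = ConduitProfile(d_ref=10.0, x_ref=1.0, b=0.2)
        assert diameter_at(p, 32.0) == pytest.approx(20.0, abs=1e-12)

    def test_power_evaluation_matches_log_space(self):
        p = ConduitProfile(d_ref=10.0, x_ref=100.0, b=0.4)
        expected = 10 ** (math.log10(10.0) + 0.4 * (math.log10(1000.0) - math.log10(100.0)))
        assert diameter_at(p, 1000.0) == pytest.approx(expected, rel=1e-12)
        assert diameter_at(p, 1000.0) == pytest.approx(25.1188643, rel=1e-6)

    def test_below_xmin_rejected(self):
        p = ConduitProfile(d_ref=10.0, x_ref=1.0, b=0.2, x_min=1.0)
        with pytest.raises(ValueError, match="x_min"):
            diameter_at(p, 0.5)

    @given(st.floats(0.01, 1.0), st.floats(1.0, 2000.0), st.floats(1.0, 2000.0))
    @settings(max_examples=50, deadline=None)
    def test_strictly_increasing_in_x(self, b, x1, x2):
        p = ConduitProfile(d_ref=10.0, x_ref=1.0, b=b, x_min=0.5)
        lo, hi = sorted((x1, x2))
        if hi > lo:
            assert diameter_at(p, hi) > diameter_at(p, lo)


class TestSegmentResistance:
    def test_formula_value(self):
        assert segment_resistance(1.0, 1.0, 1.0) == pytest.approx(128.0 / math.pi)

    def test_doubling_diameter_divides_by_16(self):
        r1 = segment_resistance(10.0, 5.0)
        r2 = segment_resistance(20.0, 5.0)
        assert r1 / r2 == pytest.approx(16.0, rel=1e-12)

    def test_linear_in_length(self):
        assert segment_resistance(7.0, 4.0) == pytest.approx(
            2.0 * segment_resistance(7.0, 2.0), rel=1e-12
        )

    @pytest.mark.parametrize("d,length", [(0.0, 1.0), (-1.0, 1.0), (1.0, 0.0)])
    def test_nonpositive_rejected(self, d, length):
        with pytest.raises(ValueError):
            segment_resistance(d, length)


class TestCumulativeResistance:
    def test_linear_when_b_zero(self):
        p = ConduitProfile(d_ref=10.0, x_ref=1.0, b=0.0)
        rp = cumulative_resistance(p, 101.0)
        per_el = segment_resistance(10.0, 1.0)
        assert rp.cumulative_resistance == pytest.approx(
            per_el * np.arange(1, len(rp.distances) + 1), rel=1e-12
        )

    def test_three_element_hand_sum(self):
        p = ConduitProfile(d_ref=10.0, x_ref=1.0, b=0.2, x_min=1.0, element_length=1.0)
        rp = cumulative_resistance(p, 4.0)
        mids = [math.sqrt(1.0 * 2.0), math.sqrt(2.0 * 3.0), math.sqrt(3.0 * 4.0)]
        hand = np.cumsum(
            [128.0 / (math.pi * (10.0 * m**0.2) ** 4) for m in mids]
        )
        assert rp.cumulative_resistance == pytest.approx(hand, rel=1e-12)
        assert rp.distances == pytest.approx([2.0, 3.0, 4.0])

    def test_too_short_path_rejected(self):
        p = ConduitProfile(d_ref=10.0, x_ref=1.0, b=0.2)
        with pytest.raises(ValueError, match="element_length"):
            cumulative_resistance(p, 1.5)

    @pytest.mark.parametrize("b", [0.0, 0.1, 0.2, 0.25, 0.4])
    def test_converges_to_analytic_integral(self, b):
        L = 500.0
        p = ConduitProfile(
            d_ref=10.0, x_ref=1.0, b=b, x_min=1.0, element_length=(L - 1.0) / 1000
        )
        discrete = cumulative_resistance(p, L).cumulative_resistance[-1]
        analytic = analytic_cumulative_resistance(p, L)
        assert discrete == pytest.approx(analytic, rel=0.01)

    def test_steeper_widening_flattens_length_dependence(self):
        # leaf-like widening (b=0.4) nearly decouples resistance from
        # path length; stem-like (b=0.2) does not
        ratios = {}
        for b in (0.2, 0.4):
            p = ConduitProfile(d_ref=10.0, x_ref=1.0, b=b)
            r = lambda L: cumulative_resistance(p, L).cumulative_resistance[-1]
            ratios[b] = r(1000.0) / r(100.0)
        assert ratios[0.4] < ratios[0.2]
        assert ratios[0.4] < 1.1  # near length-independence

    @given(st.floats(0.5, 3.0), st.floats(0.0, 0.5))
    @settings(max_examples=30, deadline=None)
    def test_scale_covariance_in_dref(self, k, b):
        p1 = ConduitProfile(d_ref=10.0, x_ref=1.0, b=b)
        pk = ConduitProfile(d_ref=10.0 * k, x_ref=1.0, b=b)
        r1 = cumulative_resistance(p1, 50.0).cumulative_resistance
        rk = cumulative_resistance(pk, 50.0).cumulative_resistance
        assert rk == pytest.approx(r1 / k**4, rel=1e-10)

    def test_monotone_increasing_in_length(self):
        p = ConduitProfile(d_ref=10.0, x_ref=1.0, b=0.3)
        r = cumulative_resistance(p, 200.0).cumulative_resistance
        assert np.all(np.diff(r) > 0)


class TestTipModels:
    def test_conductance_ratio_fourth_power(self):
        assert conductance_ratio(10.0, 20.0) == 16.0
        assert conductance_ratio(5.0, 5.0) == 1.0
        assert conductance_ratio(10.0, 30.0) == pytest.approx(81.0)

    def test_conductance_ratio_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            conductance_ratio(0.0, 10.0)

    def test_tip_diameter_worked_examples(self):
        law = TipWideningLaw(d_ref=10.0, h_ref=1.0, g=0.26)
        assert tip_diameter_at_height(law, 10.0) == pytest.approx(18.2, abs=0.05)
        assert tip_diameter_at_height(law, 20.0) == pytest.approx(21.8, abs=0.05)
        assert tip_diameter_at_height(law, 1.0) == 10.0

    def test_implied_exponent_from_anchors(self):
        assert implied_exponent((1, 10), (20, 21.8)) == pytest.approx(0.26, abs=0.005)
        assert implied_exponent((1, 10), (10, 18.2)) == pytest.approx(0.2601, abs=0.001)
        assert implied_exponent((1, 7.0), (10, 7.0)) == 0.0

    def test_implied_exponent_equal_heights_rejected(self):
        with pytest.raises(ValueError, match="differ"):
            implied_exponent((5, 10), (5, 12))

    def test_balance_matches_closed_form(self):
        for c, H in [(1.04, 10.0), (1.04, 20.0), (0.5, 7.0), (2.0, 3.0)]:
            d = balance_tip_diameter(c, H, (1.0, 10.0))
            assert d == pytest.approx(10.0 * H ** (c / 4.0), rel=1e-9)

    def test_balance_identity_cases(self):
        assert balance_tip_diameter(1.04, 1.0, (1.0, 10.0)) == pytest.approx(10.0, rel=1e-9)
        assert balance_tip_diameter(0.0, 50.0, (1.0, 10.0)) == pytest.approx(10.0, rel=1e-9)

    def test_balance_composed_with_implied_exponent(self):
        # recovering g = c/4 from two balanced points
        c = 0.8
        d10 = balance_tip_diameter(c, 10.0, (1.0, 10.0))
        d40 = balance_tip_diameter(c, 40.0, (1.0, 10.0))
        g = implied_exponent((10.0, d10), (40.0, d40))
        assert g == pytest.approx(c / 4.0, abs=1e-6)


class TestValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(d_ref=0.0, x_ref=1.0, b=0.2),
            dict(d_ref=10.0, x_ref=-1.0, b=0.2),
            dict(d_ref=10.0, x_ref=1.0, b=-0.1),
            dict(d_ref=10.0, x_ref=1.0, b=0.2, element_length=0.0),
        ],
    )
    def test_profile_invariants(self, kwargs):
        with pytest.raises(ValueError):
            ConduitProfile(**kwargs)

    def test_tip_law_invariants(self):
        with pytest.raises(ValueError):
            TipWideningLaw(d_ref=-1.0, h_ref=1.0, g=0.2)
        law = TipWideningLaw(d_ref=10.0, h_ref=1.0, g=0.2)
        with pytest.raises(ValueError):
            tip_diameter_at_height(law, 0.0)
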