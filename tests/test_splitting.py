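"""Plasma-skimming rule: coefficients, both variants, smoothing, sensitivity."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from capnet.splitting import (
    build_smoothing,
    make_split_rule,
    skimming_sensitivity,
    split_derivative,
    split_fraction,
)


@pytest.fixture(scope="module")
def rule235():
    """Rule at the equal-diameter node (parent D=20, H=0.45)."""
    return make_split_rule(20.0, 20.0, 20.0, 0.45)


@pytest.fixture(scope="module")
def rule235_smooth(rule235):
    return build_smoothing(rule235)


class TestCoefficients:
    def test_equal_daughters_have_no_asymmetry(self, rule235):
        assert rule235.A == 0.0

    def test_printed_coefficients(self, rule235):
        assert rule235.B == pytest.approx(1.0 + 6.98 * 0.55 / 20.0, rel=1e-12)
        assert rule235.B == pytest.approx(1.19195, abs=1e-5)
        assert rule235.psi0 == pytest.approx(0.02, rel=1e-12)

    def test_narrow_parent_raises_threshold(self):
        # node 1-3-4 with alpha = 0.5: parent diameter 10 -> psi0 = 0.04
        r = make_split_rule(10.0, 20.0, 10.0, 0.45)
        assert r.psi0 == pytest.approx(0.04, rel=1e-12)

    def test_bad_inputs(self):
        with pytest.raises(ValueError):
            make_split_rule(1.0, 20.0, 20.0, 0.45)
        with pytest.raises(ValueError):
            make_split_rule(20.0, 20.0, 20.0, 1.2)


class TestSplitFraction:
    def test_symmetric_midpoint(self, rule235):
        assert split_fraction(rule235, 0.5) == pytest.approx(0.5, rel=1e-12)

    def test_below_threshold_no_red_cells(self, rule235):
        assert split_fraction(rule235, rule235.psi0 / 2) == 0.0
        assert split_fraction(rule235, 1.0 - rule235.psi0 / 2) == 1.0

    def test_interior_value(self, rule235):
        # (0.28)^B / ((0.28)^B + (0.68)^B) with B = 1.19195
        B = rule235.B
        expect = 0.28**B / (0.28**B + 0.68**B)
        assert split_fraction(rule235, 0.3) == pytest.approx(expect, rel=1e-12)
        assert expect == pytest.approx(0.2577, abs=1e-4)

    @pytest.mark.parametrize("variant", ["nonsmooth", "smooth"])
    def test_monotone_nondecreasing(self, rule235, rule235_smooth, variant):
        rule = rule235 if variant == "nonsmooth" else rule235_smooth
        grid = [k / 400 for k in range(401)]
        vals = [split_fraction(rule, p) for p in grid]
        assert all(b >= a for a, b in zip(vals, vals[1:]))

    @given(psi=st.floats(0.0, 1.0))
    @settings(max_examples=200, deadline=None)
    def test_point_symmetry_of_equal_daughter_rule(self, rule235, psi):
        # A = 0 makes F(psi) + F(1 - psi) = 1 (haematocrit conservation
        # between the two daughters of a symmetric bifurcation)
        total = split_fraction(rule235, psi) + split_fraction(rule235, 1.0 - psi)
        assert total == pytest.approx(1.0, abs=1e-12)

    def test_domain_error(self, rule235):
        with pytest.raises(ValueError):
            split_fraction(rule235, 1.2)


class TestSplitDerivative:
    def test_zero_on_constant_pieces(self, rule235):
        assert split_derivative(rule235, 0.005) == 0.0
        assert split_derivative(rule235, 0.995) == 0.0

    @pytest.mark.parametrize("psi", [0.1, 0.3, 0.5, 0.7, 0.9])
    def test_matches_finite_difference(self, rule235, psi):
        h = 1e-7
        fd = (split_fraction(rule235, psi + h) - split_fraction(rule235, psi - h)) / (2 * h)
        assert split_derivative(rule235, psi) == pytest.approx(fd, rel=1e-6)

    @pytest.mark.parametrize("psi", [0.01, 0.05, 0.3, 0.6, 0.98])
    def test_smooth_variant_finite_difference(self, rule235_smooth, psi):
        h = 1e-7
        fd = (split_fraction(rule235_smooth, psi + h)
              - split_fraction(rule235_smooth, psi - h)) / (2 * h)
        assert split_derivative(rule235_smooth, psi) == pytest.approx(fd, rel=1e-5)


class TestSmoothing:
    def test_origin_conditions(self, rule235_smooth):
        r = rule235_smooth
        assert split_fraction(r, 0.0) == 0.0
        assert split_derivative(r, 0.0) == 0.0
        # F''(0) = 0 for the cubic a*psi^3: the second difference at the
        # origin is 6*a*h, vanishing linearly with the step
        h = 1e-5
        f2 = (split_fraction(r, 2 * h) - 2 * split_fraction(r, h)) / h**2
        assert abs(f2) <= 7.0 * r.a * h

    def test_c1_continuity_at_junctions(self, rule235, rule235_smooth):
        r = rule235_smooth
        for psi in (r.psiL, r.psiU):
            assert split_fraction(rule235, psi) == pytest.approx(
                split_fraction(r, psi), abs=1e-10)
            assert split_derivative(rule235, psi) == pytest.approx(
                split_derivative(r, psi), abs=1e-10)

    def test_core_unchanged(self, rule235, rule235_smooth):
        mid = 0.5 * (rule235_smooth.psiL + rule235_smooth.psiU)
        assert split_fraction(rule235, mid) == split_fraction(rule235_smooth, mid)

    def test_asymmetric_rule_smoothable(self):
        # node 1-3-4 rule with unequal daughters (A != 0)
        r = make_split_rule(0.6 * 20.0, 20.0, 0.6 * 20.0, 0.5)
        s = build_smoothing(r)
        assert r.psi0 < s.psiL < s.psiU < 1.0 - r.psi0
        assert split_fraction(r, s.psiL) == pytest.approx(
            split_fraction(s, s.psiL), abs=1e-10)


class TestSensitivity:
    def test_zero_below_threshold(self, rule235):
        assert skimming_sensitivity(rule235, 0.01) == 0.0
        assert skimming_sensitivity(rule235, 0.0) == 0.0

    def test_cubic_region_closed_form(self, rule235_smooth):
        # y = a psi^3 gives S = -(1/psi)(a psi^2 - 3 a psi^2) = 2 a psi
        r = rule235_smooth
        psi = 0.5 * r.psiL
        assert skimming_sensitivity(r, psi) == pytest.approx(
            2.0 * r.a * psi, rel=1e-10)

    def test_nonsmooth_exceeds_smooth_above_threshold(self, rule235, rule235_smooth):
        psi = rule235.psi0 * 1.25
        assert (skimming_sensitivity(rule235, psi)
                > skimming_sensitivity(rule235_smooth, psi) > 0.0)
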