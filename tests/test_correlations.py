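import warnings

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.optimize import brentq

from algalipid.correlations import (
    ExtrapolationWarning,
    QuadraticFit,
    final_lipid,
    fit_h0_linear,
    fit_xmax_quadratic,
    predict_xmax,
    relative_increase,
)

from conftest import PAPER_H0_LINE, PAPER_QUAD, TABLE1_H0, TABLE1_XMAX


def paper_fit() -> QuadraticFit:
    """The published quadratic, wrapped for prediction helpers."""
    a2, a1, a0 = PAPER_QUAD
    return QuadraticFit(a2=a2, a1=a1, a0=a0, r_squared=0.9982, n=5, n0_min=0.075, n0_max=0.9)


class TestXmaxQuadratic:
    def test_reproduces_published_fit_within_input_rounding(self):
        """OLS on the five per-condition means recovers the published quadratic.

        The published coefficients come from unrounded estimates; rounding the
        five inputs to 3 decimals can move a2/a1 by up to ~0.007 and a0 by
        ~0.0011 (pseudoinverse row-norm bound), which is the agreement a
        re-fit of the printed values can support.
        """
        fit = fit_xmax_quadratic(TABLE1_XMAX)
        assert fit.a2 == pytest.approx(PAPER_QUAD[0], abs=7.5e-3)
        assert fit.a1 == pytest.approx(PAPER_QUAD[1], abs=7.5e-3)
        assert fit.a0 == pytest.approx(PAPER_QUAD[2], abs=1.6e-3)
        assert round(fit.a2, 2) == round(PAPER_QUAD[0], 2)
        assert round(fit.a1, 2) == round(PAPER_QUAD[1], 2)
        assert round(fit.a0, 2) == round(PAPER_QUAD[2], 2)
        assert fit.r_squared == pytest.approx(0.9982, abs=5e-5)

    def test_exact_quadratic_is_interpolated(self):
        xs = np.array([0.1, 0.4, 0.7, 1.0])
        pairs = np.column_stack([xs, -2 * xs**2 + 3 * xs + 1])
        fit = fit_xmax_quadratic(pairs)
        assert (fit.a2, fit.a1, fit.a0) == pytest.approx((-2.0, 3.0, 1.0), abs=1e-10)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_three_noncollinear_points_fit_exactly(self):
        fit = fit_xmax_quadratic([(0.1, 1.0), (0.5, 3.0), (0.9, 2.0)])
        assert fit.r_squared == pytest.approx(1.0, abs=1e-10)

    def test_rank_deficient_design_rejected(self):
        with pytest.raises(ValueError):
            fit_xmax_quadratic([(0.1, 1.0), (0.1, 1.2), (0.1, 0.9)])
        with pytest.raises(ValueError):
            fit_xmax_quadratic([(0.1, 1.0), (0.2, 1.2)])


class TestH0Line:
    def test_reproduces_published_line(self):
        fit = fit_h0_linear(TABLE1_H0)
        assert fit.slope == pytest.approx(PAPER_H0_LINE[0], abs=5e-3)
        assert fit.intercept == pytest.approx(PAPER_H0_LINE[1], abs=5e-5)

    def test_two_points_interpolated(self):
        fit = fit_h0_linear([(0.1, -0.5), (0.9, -1.3)])
        assert fit.slope == pytest.approx(-1.0)
        assert fit.intercept == pytest.approx(-0.4)
        assert fit.r_squared == pytest.approx(1.0)

    def test_constant_response_gives_zero_slope(self):
        fit = fit_h0_linear([(0.1, -0.7), (0.5, -0.7), (0.9, -0.7)])
        assert fit.slope == pytest.approx(0.0, abs=1e-12)
        assert fit.intercept == pytest.approx(-0.7)

    def test_degenerate_design_rejected(self):
        with pytest.raises(ValueError):
            fit_h0_linear([(0.3, -1.0), (0.3, -1.2)])


class TestPredictions:
    @pytest.mark.parametrize("n0, expected", [(0.9, 6.710), (0.6, 6.040), (0.0, 0.439)])
    def test_published_curve_values(self, n0, expected):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ExtrapolationWarning)
            assert predict_xmax(n0, paper_fit()) == pytest.approx(expected, abs=1e-3)

    def test_extrapolation_warns(self):
        with pytest.warns(ExtrapolationWarning):
            predict_xmax(1.5, paper_fit())
        with warnings.catch_warnings():
            warnings.simplefilter("error")
            predict_xmax(0.5, paper_fit())  # interior: no warning

    def test_final_lipid_published_anchor(self):
        # printed formula uses 0.0495 as the additive constant itself
        lf = final_lipid(0.9, k=2.120, c=0.44, phi=0.0495, fit=paper_fit(), phi_times_k=False)
        assert lf == pytest.approx(0.268, abs=1e-3)

    def test_final_lipid_default_reading_scales_phi_by_k(self):
        lf = final_lipid(0.9, k=2.120, c=0.44, phi=0.0495 / 2.120, fit=paper_fit())
        assert lf == pytest.approx(0.268, abs=1e-3)

    def test_final_lipid_root_and_composition_limit(self):
        fit = paper_fit()
        root = brentq(
            lambda n0: final_lipid(n0, 2.120, 0.44, 0.0234, fit), 0.9, 1.6
        )
        assert final_lipid(root, 2.120, 0.44, 0.0234, fit) == pytest.approx(0.0, abs=1e-12)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ExtrapolationWarning)
            assert final_lipid(0.4, 1e-9, 0.44, 0.0, fit) == pytest.approx(0.56, abs=1e-8)

    def test_final_lipid_monotone_in_k_and_phi(self):
        fit = paper_fit()
        base = final_lipid(0.6, 2.0, 0.44, 0.03, fit)
        assert final_lipid(0.6, 2.2, 0.44, 0.03, fit) < base
        assert final_lipid(0.6, 2.0, 0.44, 0.05, fit) < base
        # larger predicted Xmax dilutes the quota and raises final lipid
        bigger = QuadraticFit(fit.a2, fit.a1, fit.a0 + 1.0, 1.0, 5, 0.075, 0.9)
        assert final_lipid(0.6, 2.0, 0.44, 0.03, bigger) > base

    def test_final_lipid_rejects_nonpositive_xmax(self):
        with pytest.raises(ValueError), warnings.catch_warnings():
            warnings.simplefilter("ignore", ExtrapolationWarning)
            final_lipid(5.0, 2.0, 0.44, 0.03, paper_fit())


class TestRelativeIncrease:
    def test_published_increase_low_to_high(self):
        assert relative_increase(0.6, 0.9, paper_fit()) == pytest.approx(11.1, abs=0.1)

    def test_low_range_increase(self):
        assert relative_increase(0.075, 0.3, paper_fit()) == pytest.approx(172.4, abs=0.2)

    def test_identity_is_zero(self):
        assert relative_increase(0.42, 0.42, paper_fit()) == 0.0

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(a=st.floats(0.1, 0.9), b=st.floats(0.1, 0.9))
    def test_forward_backward_reciprocal(self, a, b):
        fit = paper_fit()
        r_ab = relative_increase(a, b, fit)
        r_ba = relative_increase(b, a, fit)
        assert (1 + r_ab / 100) * (1 + r_ba / 100) == pytest.approx(1.0, rel=1e-10)
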