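"""Closed-form ratio-variable correlations, their singularities, and
Monte-Carlo oracle agreement."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pctchange import (
    ApproximationWarning,
    NullBasis,
    RatioMoments,
    UndefinedCorrelationError,
    appropriate_null,
    approx_corr_index_ratios,
    chayes_null,
    corr_surface_k,
    corr_x_vs_negyx,
)


def mc_corr_shared_denominator(rng, cv, r_xy, n=1_000_000):
    """Brute-force oracle: empirical corr(x/z, y/z) for normal triples
    with common mean 1, SD = cv and corr(x, y) = r_xy, z independent."""
    z1 = rng.standard_normal(n)
    x = 1.0 + cv * z1
    y = 1.0 + cv * (r_xy * z1 + math.sqrt(1 - r_xy**2) * rng.standard_normal(n))
    z = 1.0 + cv * rng.standard_normal(n)
    return float(np.corrcoef(x / z, y / z)[0, 1])


def mc_corr_baseline_pctchange(rng, cv_x, cv_y, r_xy, n=1_000_000):
    """Brute-force oracle: empirical corr(x, (x - y)/x) for bivariate
    normal pairs with means 1, the given CVs and correlation."""
    z1 = rng.standard_normal(n)
    x = 1.0 + cv_x * z1
    y = 1.0 + cv_y * (r_xy * z1 + math.sqrt(1 - r_xy**2) * rng.standard_normal(n))
    return float(np.corrcoef(x, (x - y) / x)[0, 1])


class TestGeneralFormula:
    def test_shared_denominator_equal_cvs_gives_half(self):
        """Three mutually uncorrelated variables with equal CVs: the
        index correlation x/z vs y/z is 0.5."""
        m = RatioMoments(cv_x=0.1, cv_y=0.1, cv_z=0.1, cv_w=0.1, r_zw=1.0)
        assert approx_corr_index_ratios(m) == pytest.approx(0.5)

    def test_constant_denominators_reduce_to_r_xy(self):
        m = RatioMoments(cv_x=0.2, cv_y=0.3, cv_z=0.0, cv_w=0.0, r_xy=0.42)
        assert approx_corr_index_ratios(m) == pytest.approx(0.42)

    def test_zero_variance_ratio_is_undefined(self):
        # x/z with cv_x = cv_z and r_xz = 1: the ratio is constant
        m = RatioMoments(cv_x=0.1, cv_y=0.2, cv_z=0.1, cv_w=0.0, r_xz=1.0)
        with pytest.raises(UndefinedCorrelationError):
            approx_corr_index_ratios(m)

    def test_large_cv_warns(self):
        m = RatioMoments(cv_x=0.7, cv_y=0.1, cv_z=0.1, cv_w=0.1, r_zw=1.0)
        with pytest.warns(ApproximationWarning):
            approx_corr_index_ratios(m)

    def test_divergent_cv_is_rejected(self):
        with pytest.raises(ValueError, match="converge"):
            RatioMoments(cv_x=0.1, cv_y=0.1, cv_z=1.2, cv_w=0.1)

    def test_monte_carlo_oracle_shared_denominator(self, rng):
        """At small CVs the formula tracks simulation within 0.01."""
        m = RatioMoments(cv_x=0.05, cv_y=0.05, cv_z=0.05, cv_w=0.05,
                         r_zw=1.0)
        analytic = approx_corr_index_ratios(m)
        empirical = mc_corr_shared_denominator(rng, cv=0.05, r_xy=0.0)
        assert analytic == pytest.approx(empirical, abs=0.01)


class TestCorrXNegYX:
    def test_equal_cvs_uncorrelated_gives_inv_sqrt2(self):
        assert corr_x_vs_negyx(0.1, 0.1, 0.0) == pytest.approx(1 / math.sqrt(2))

    def test_perfect_correlation_with_larger_baseline_cv(self):
        assert corr_x_vs_negyx(0.2, 0.1, 1.0) == pytest.approx(1.0)

    def test_printed_toy_cvs(self):
        assert corr_x_vs_negyx(0.099, 0.052, 0.0) == pytest.approx(0.885, abs=0.001)

    def test_singular_when_cvs_equal_and_r_one(self):
        with pytest.raises(UndefinedCorrelationError):
            corr_x_vs_negyx(0.1, 0.1, 1.0)

    @pytest.mark.parametrize("r_xy", [-0.5, 0.0, 0.25, 0.5, 0.75])
    @pytest.mark.parametrize("k", [0.5, 1.0, 2.0])
    def test_monte_carlo_oracle_grid(self, rng, r_xy, k):
        """Formula vs simulation within 0.02 across the (r_xy, k) grid at
        CVs at or below 0.1."""
        cv_y = 0.05
        cv_x = k * cv_y
        analytic = corr_x_vs_negyx(cv_x, cv_y, r_xy)
        empirical = mc_corr_baseline_pctchange(rng, cv_x, cv_y, r_xy)
        assert analytic == pytest.approx(empirical, abs=0.02)


class TestCorrSurfaceK:
    def test_r_minus_one_always_minus_one(self):
        for k in (0.1, 0.5, 1.0, 2.0, 10.0):
            assert corr_surface_k(k, -1.0) == pytest.approx(-1.0)

    def test_singularity_structure_at_r_one(self):
        with pytest.raises(UndefinedCorrelationError):
            corr_surface_k(1.0, 1.0)
        assert corr_surface_k(0.5, 1.0) == 1.0
        assert corr_surface_k(2.0, 1.0) == -1.0

    def test_k_one_r_zero(self):
        assert corr_surface_k(1.0, 0.0) == pytest.approx(-1 / math.sqrt(2))

    def test_k_limits_at_r_zero(self):
        """At r_xy = 0 the surface spans (0, -1) as k goes 0 -> inf."""
        assert corr_surface_k(1e-6, 0.0) == pytest.approx(0.0, abs=1e-5)
        assert corr_surface_k(1e6, 0.0) == pytest.approx(-1.0, abs=1e-5)

    def test_rejects_nonpositive_k(self):
        with pytest.raises(ValueError):
            corr_surface_k(0.0, 0.3)

    @given(k=st.floats(min_value=0.01, max_value=100.0),
           r=st.floats(min_value=-1.0, max_value=0.999999))
    @settings(max_examples=300, deadline=None)
    def test_output_always_in_unit_interval(self, k, r):
        assert -1.0 <= corr_surface_k(k, r) <= 1.0


class TestNulls:
    def test_chayes_equal_cvs(self):
        assert chayes_null(0.1, 0.1) == pytest.approx(-1 / math.sqrt(2))
        assert chayes_null(0.3, 0.3) == pytest.approx(corr_surface_k(1.0, 0.0))

    def test_chayes_vanishing_baseline_cv(self):
        assert chayes_null(1e-9, 0.1) == pytest.approx(0.0, abs=1e-6)

    def test_chayes_closed_form(self, rng):
        val = chayes_null(0.2, 0.1)
        assert val == pytest.approx(-0.2 / math.sqrt(0.05), abs=1e-12)
        assert val == pytest.approx(-0.894, abs=0.001)
        # The null depends on the CVs only through their ratio; simulate
        # the cross-check at CVs <= 0.1 where the first-order formula is
        # accurate (at CV 0.2 the approximation itself drifts by ~0.05).
        empirical = mc_corr_baseline_pctchange(rng, 0.1, 0.05, 0.0)
        assert -val == pytest.approx(empirical, abs=0.02)

    @pytest.mark.parametrize("r_xy,expected,tol", [
        (0.207, 0.63, 0.005),
        (0.484, 0.508, 0.005),
        (0.0, 1 / math.sqrt(2), 1e-12),
    ])
    def test_appropriate_null_values(self, r_xy, expected, tol):
        spec = appropriate_null(r_xy)
        assert spec.rho0 == pytest.approx(expected, abs=tol)
        assert spec.basis is NullBasis.APPROPRIATE_K1
        assert spec.r_xy_used == r_xy

    def test_appropriate_null_singular_at_one(self):
        with pytest.raises(UndefinedCorrelationError):
            appropriate_null(1.0)

    def test_appropriate_null_degenerate_at_minus_one(self):
        with pytest.warns(ApproximationWarning):
            spec = appropriate_null(-1.0)
        assert spec.rho0 == 1.0

    def test_identity_with_surface_on_dense_grid(self):
        """rho0(r) = -corr_surface_k(1, r) to machine precision."""
        for r in np.linspace(-0.999, 0.999, 1000):
            assert appropriate_null(float(r)).rho0 == pytest.approx(
                -corr_surface_k(1.0, float(r)), abs=1e-13)

    def test_strictly_decreasing_in_r(self):
        grid = np.linspace(-0.999, 0.999, 500)
        vals = [appropriate_null(float(r)).rho0 for r in grid]
        assert all(a > b for a, b in zip(vals, vals[1:]))
        assert all(0.0 < v < 1.0 for v in vals)
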