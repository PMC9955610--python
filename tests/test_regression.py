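"""Line-fitting engines: hand-computed cases, geometry, and oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bcivalidate.datatypes import DegenerateInputError
from bcivalidate.regression import (
    adjusted_r2,
    common_slope_test,
    fit_ma,
    fit_ols,
    fit_sma,
)

from oracles import brute_ma, brute_ols, brute_sma


X3, Y3 = [1.0, 2.0, 3.0], [1.0, 3.0, 2.0]


class TestHandExamples:
    def test_ols_small(self):
        f = fit_ols(X3, Y3)
        assert f.slope == pytest.approx(0.5)
        assert f.intercept == pytest.approx(1.0)

    def test_sma_small(self):
        # sd(y) = sd(x) here and covariance positive -> slope exactly 1
        f = fit_sma(X3, Y3)
        assert f.slope == pytest.approx(1.0)
        assert f.intercept == pytest.approx(0.0)

    def test_ma_small(self):
        # Syy = Sxx makes the major axis the 45-degree line
        f = fit_ma(X3, Y3)
        assert f.slope == pytest.approx(1.0)

    def test_exact_line(self):
        x = np.arange(1.0, 8.0)
        f = fit_ols(x, 2 * x + 1)
        assert (f.slope, f.intercept, f.r2) == pytest.approx((2.0, 1.0, 1.0))
        g = fit_ma(x, 5 * x)
        assert g.slope == pytest.approx(5.0)

    def test_negative_perfect_sma_ci_collapses(self):
        x = np.arange(1.0, 6.0)
        f = fit_sma(x, -3 * x)
        assert f.slope == pytest.approx(-3.0)
        assert f.r2 == pytest.approx(1.0)
        assert f.slope_ci[0] == pytest.approx(-3.0)
        assert f.slope_ci[1] == pytest.approx(-3.0)

    def test_adjusted_r2_values(self):
        assert adjusted_r2(1.0, 50) == pytest.approx(1.0)
        assert adjusted_r2(0.5, 3, 1) == pytest.approx(0.0)
        assert adjusted_r2(0.37, 883, 1) == pytest.approx(0.3692849, abs=1e-6)
        with pytest.raises(DegenerateInputError):
            adjusted_r2(0.5, 2, 1)


class TestDegenerateInputs:
    def test_constant_x(self):
        with pytest.raises(DegenerateInputError):
            fit_ols([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_zero_correlation_sma(self):
        # symmetric cross: covariance exactly zero
        with pytest.raises(DegenerateInputError):
            fit_sma([-1.0, 1.0, 0.0, 0.0], [0.0, 0.0, -1.0, 1.0])

    def test_too_few_points(self):
        with pytest.raises(DegenerateInputError):
            fit_sma([1.0, 2.0], [1.0, 2.0])


class TestGeometry:
    def test_sma_axis_swap_reciprocal(self, rng):
        x = rng.normal(0, 1, 40)
        y = 2.0 * x + rng.normal(0, 0.5, 40)
        assert fit_sma(y, x).slope == pytest.approx(1.0 / fit_sma(x, y).slope)

    def test_ma_rotation_by_90_degrees(self, rng):
        x = rng.normal(0, 1, 40)
        y = 0.7 * x + rng.normal(0, 0.3, 40)
        b = fit_ma(x, y).slope
        # rotate the centred cloud a quarter turn: slope maps to -1/b
        xc, yc = x - x.mean(), y - y.mean()
        b_rot = fit_ma(-yc, xc).slope
        assert b_rot == pytest.approx(-1.0 / b)

    def test_all_methods_agree_on_collinear_data(self):
        x = np.linspace(1, 9, 12)
        y = 0.8 * x - 2.0
        for fit in (fit_ols, fit_ma, fit_sma):
            f = fit(x, y)
            assert f.slope == pytest.approx(0.8, abs=1e-12)
            assert f.intercept == pytest.approx(-2.0, abs=1e-10)

    def test_invariants_on_noisy_data(self, rng):
        x = rng.normal(3, 0.4, 60)
        y = 3.1 * x + rng.normal(0, 0.5, 60)
        ols, sma = fit_ols(x, y), fit_sma(x, y)
        assert abs(ols.slope) <= abs(sma.slope)
        # geometric-mean property: b_sma^2 = b_ols(y~x) / b_ols(x~y)^{-1}... i.e.
        # |b_sma| = sqrt(b_ols / (1/b_ols_xy))
        b_xy = fit_ols(y, x).slope
        assert sma.slope**2 == pytest.approx(ols.slope / b_xy)
        for f in (ols, sma, fit_ma(x, y)):
            assert abs(f.residuals.sum()) < 1e-9 * np.abs(y).sum()
            assert f.intercept == pytest.approx(y.mean() - f.slope * x.mean())
            assert f.slope_ci[0] <= f.slope <= f.slope_ci[1]


@settings(max_examples=30, deadline=None, derandomize=True)
@given(st.integers(min_value=0, max_value=10_000))
def test_sma_equals_ols_over_r_property(seed):
    """|b_sma| = |b_ols| / |r| exactly, on arbitrary non-degenerate data."""
    rng = np.random.default_rng(seed)
    n = int(rng.integers(4, 30))
    x = rng.normal(0, 1 + rng.random(), n)
    y = rng.normal(0, 2, n) + rng.normal(-2, 2) * x
    try:
        sma, ols = fit_sma(x, y), fit_ols(x, y)
    except DegenerateInputError:
        return
    r = math.sqrt(ols.r2)
    assert abs(sma.slope) == pytest.approx(abs(ols.slope) / r)


def test_slopes_match_brute_force_loss_minimizers():
    """OLS/MA/SMA closed forms agree with direct loss minimization.

    100 random small datasets; vertical squares, orthogonal squares and
    triangle areas respectively, minimized numerically.
    """
    rng = np.random.default_rng(2024)
    checked = 0
    while checked < 100:
        n = int(rng.integers(4, 13))
        x = rng.normal(0, 1, n)
        y = rng.normal(-1.5, 1.5) * x + rng.normal(0, 0.8, n)
        try:
            fits = (fit_ols(x, y), fit_ma(x, y), fit_sma(x, y))
        except DegenerateInputError:
            continue
        if fits[0].r2 < 0.05:  # nearly-uncorrelated clouds: SMA loss is flat
            continue
        for fit, brute in zip(fits, (brute_ols, brute_ma, brute_sma)):
            a, b = brute(x, y)
            assert fit.slope == pytest.approx(b, abs=1e-6), fit.method
            assert fit.intercept == pytest.approx(a, abs=1e-6), fit.method
        checked += 1


class TestCommonSlope:
    def test_identical_groups_give_null_result(self, rng):
        x = rng.normal(0, 1, 50)
        y = 2 * x + rng.normal(0, 0.3, 50)
        t = common_slope_test([(x, y), (x, y)])
        assert t.lr_stat == pytest.approx(0.0, abs=1e-6)
        assert t.p_value == pytest.approx(1.0, abs=1e-3)
        assert t.common_slope == pytest.approx(fit_sma(x, y).slope, rel=1e-3)

    def test_detects_different_slopes(self):
        """Groups generated with slopes 3 vs 6 at n=200: p < 0.001 in >=99% of runs."""
        rng = np.random.default_rng(99)
        hits = 0
        runs = 200
        for _ in range(runs):
            groups = []
            for b in (3.0, 6.0):
                x = rng.normal(0, 1, 200)
                y = b * (0.9 * x + math.sqrt(1 - 0.81) * rng.normal(0, 1, 200))
                groups.append((x, y))
            hits += common_slope_test(groups).p_value < 0.001
        assert hits >= 0.99 * runs

    def test_degenerate_group_named(self):
        x = np.arange(5.0)
        with pytest.raises(DegenerateInputError, match="group 1"):
            common_slope_test([(x, 2 * x + 0.1 * np.sin(x)), (x, np.ones(5))])
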