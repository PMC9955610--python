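"""Straight-line fitting engines for allometry.

Three estimators of the line ln M = ln a + b ln L are provided:

* **OLS** — ordinary least squares, minimizing vertical squared
  deviations; appropriate when the predictor is measured without error.
* **MA** — major axis, minimizing orthogonal squared deviations.
* **SMA** — standardized major axis, minimizing the summed triangle
  areas between points and line; its slope is sign(r) · sd(y)/sd(x),
  the geometric mean of the OLS slope of y on x and the reciprocal OLS
  slope of x on y. SMA is the conventional choice for allometric
  scaling exponents because both mass and length carry natural
  variability and measurement error.

All three report *vertical* residuals y − (a + b x), so residual-based
condition indices computed from them live on a common scale, and the
line always passes through the centroid (x̄, ȳ).

A likelihood-ratio test for a common SMA slope across groups is
included: for candidate slope b the SMA residual scores u = y − b x
and fitted-axis scores v = y + b x are uncorrelated within a group
exactly when b is that group's SMA slope, so −Σ nᵢ ln(1 − r²_{uv,i}(b))
minimized over b is twice the log-likelihood-ratio against separate
slopes and is referred to χ² with (groups − 1) degrees of freedom.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np
from scipy import optimize, stats

from .datatypes import CommonSlopeTest, DegenerateInputError, LineFit

__all__ = [
    "fit_ols",
    "fit_ma",
    "fit_sma",
    "adjusted_r2",
    "common_slope_test",
]


def _prepare(x, y, min_n: int = 3):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise DegenerateInputError("x and y must be 1-d arrays of equal length")
    if len(x) < min_n:
        raise DegenerateInputError(f"need at least {min_n} points, got {len(x)}")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise DegenerateInputError("non-finite values in input")
    return x, y


def _moments(x, y):
    """Centred sums of squares and cross-products."""
    xbar = x.mean()
    ybar = y.mean()
    dx = x - xbar
    dy = y - ybar
    return xbar, ybar, float(dx @ dx), float(dy @ dy), float(dx @ dy)


def adjusted_r2(r2: float, n: int, n_predictors: int = 1) -> float:
    """Adjusted coefficient of determination.

    1 − (1 − r²)(n − 1)/(n − p − 1); penalizes model size.
    """
    if n <= n_predictors + 1:
        raise DegenerateInputError("n must exceed n_predictors + 1 for adjusted r^2")
    return 1.0 - (1.0 - r2) * (n - 1) / (n - n_predictors - 1)


def _finish(method, x, y, slope, intercept, n, r2, slope_ci) -> LineFit:
    residuals = y - (intercept + slope * x)
    return LineFit(
        method=method,
        slope=float(slope),
        intercept=float(intercept),
        n=n,
        r2=float(r2),
        adj_r2=float(adjusted_r2(r2, n, 1)),
        slope_ci=(float(min(slope_ci)), float(max(slope_ci))),
        residuals=residuals,
    )


def fit_ols(x, y) -> LineFit:
    """Ordinary least-squares line of y on x.

    Slope Sxy/Sxx; 95% CI from the t distribution on n − 2 df.
    """
    x, y = _prepare(x, y)
    n = len(x)
    xbar, ybar, sxx, syy, sxy = _moments(x, y)
    if sxx <= 0:
        raise DegenerateInputError("x is constant; OLS slope undefined")
    b = sxy / sxx
    a = ybar - b * xbar
    r2 = 0.0 if syy == 0 else min(sxy * sxy / (sxx * syy), 1.0)
    sse = max(syy - b * sxy, 0.0)
    se_b = math.sqrt(sse / (n - 2) / sxx)
    tcrit = stats.t.ppf(0.975, n - 2)
    ci = (b - tcrit * se_b, b + tcrit * se_b)
    return _finish("ols", x, y, b, a, n, r2, ci)


def fit_sma(x, y) -> LineFit:
    """Standardized major axis line of y on x.

    Slope sign(r) · sd(y)/sd(x); 95% CI by the F-statistic construction
    b · (√(B + 1) ± √B) with B = F₀.₉₅(1, n−2) (1 − r²)/(n − 2).
    """
    x, y = _prepare(x, y)
    n = len(x)
    xbar, ybar, sxx, syy, sxy = _moments(x, y)
    if sxx <= 0 or syy <= 0:
        raise DegenerateInputError("constant variable; SMA slope undefined")
    r2 = min(sxy * sxy / (sxx * syy), 1.0)
    if sxy == 0:
        raise DegenerateInputError("zero correlation; SMA slope sign undefined")
    b = math.copysign(math.sqrt(syy / sxx), sxy)
    a = ybar - b * xbar
    B = stats.f.ppf(0.95, 1, n - 2) * (1.0 - r2) / (n - 2)
    ci = (b * (math.sqrt(B + 1.0) - math.sqrt(B)), b * (math.sqrt(B + 1.0) + math.sqrt(B)))
    return _finish("sma", x, y, b, a, n, r2, ci)


def fit_ma(x, y) -> LineFit:
    """Major axis line of y on x (first principal axis).

    Slope (Syy − Sxx + √((Syy − Sxx)² + 4 Sxy²)) / (2 Sxy); 95% CI by
    Jolicoeur's eigenvalue construction on the axis angle.
    """
    x, y = _prepare(x, y)
    n = len(x)
    xbar, ybar, sxx, syy, sxy = _moments(x, y)
    if sxx <= 0 or syy <= 0:
        raise DegenerateInputError("constant variable; MA slope undefined")
    if sxy == 0:
        raise DegenerateInputError("zero covariance; MA slope undefined")
    r2 = min(sxy * sxy / (sxx * syy), 1.0)
    b = (syy - sxx + math.sqrt((syy - sxx) ** 2 + 4.0 * sxy * sxy)) / (2.0 * sxy)
    a = ybar - b * xbar
    # Jolicoeur-style CI via the eigenvalues of the covariance matrix:
    # H = F / ((l1/l2 + l2/l1 - 2)(n-2)); half-angle phi = atan sqrt(H/(1-H)).
    tr = sxx + syy
    det = sxx * syy - sxy * sxy
    disc = math.sqrt(max(tr * tr - 4.0 * det, 0.0))
    l1 = (tr + disc) / 2.0
    l2 = (tr - disc) / 2.0
    if l2 <= 0:  # perfectly collinear data
        ci = (b, b)
    else:
        F = stats.f.ppf(0.95, 1, n - 2)
        H = F / ((l1 / l2 + l2 / l1 - 2.0) * (n - 2))
        if H >= 1.0:
            ci = (-math.inf, math.inf)
        else:
            theta = math.atan(b)
            phi = math.atan(math.sqrt(H / (1.0 - H)))
            ci = (math.tan(theta - phi), math.tan(theta + phi))
    return _finish("ma", x, y, b, a, n, r2, ci)


def _group_moments(groups: Sequence):
    out = []
    for i, (x, y) in enumerate(groups):
        try:
            x, y = _prepare(x, y)
            _, _, sxx, syy, sxy = _moments(x, y)
            if sxx <= 0 or syy <= 0 or sxy == 0:
                raise DegenerateInputError("constant variable or zero correlation")
        except DegenerateInputError as exc:
            raise DegenerateInputError(f"group {i}: {exc}") from exc
        out.append((len(x), sxx, syy, sxy))
    return out


def common_slope_test(groups: Sequence) -> CommonSlopeTest:
    """Likelihood-ratio test for a common SMA slope across groups.

    ``groups`` is a sequence of (x, y) pairs, each with n ≥ 3 and a
    valid SMA fit. Returns the LR statistic, its χ² p-value on
    (groups − 1) df, and the pooled common-slope estimate.
    """
    if len(groups) < 2:
        raise DegenerateInputError("need at least two groups")
    moments = _group_moments(groups)
    signs = {math.copysign(1.0, sxy) for (_, _, _, sxy) in moments}
    if len(signs) > 1:
        raise DegenerateInputError("groups disagree on the sign of the slope")
    sign = signs.pop()

    slopes = [sign * math.sqrt(syy / sxx) for (_, sxx, syy, _) in moments]

    def neg2ll(logb: float) -> float:
        b = sign * math.exp(logb)
        total = 0.0
        for n_i, sxx, syy, sxy in moments:
            var_u = syy - 2.0 * b * sxy + b * b * sxx  # residual scores y - bx
            var_v = syy + 2.0 * b * sxy + b * b * sxx  # axis scores y + bx
            cov_uv = syy - b * b * sxx
            r2_uv = cov_uv * cov_uv / (var_u * var_v)
            r2_uv = min(r2_uv, 1.0 - 1e-15)
            total += -n_i * math.log1p(-r2_uv)
        return total

    lo = math.log(min(abs(s) for s in slopes)) - 2.0
    hi = math.log(max(abs(s) for s in slopes)) + 2.0
    res = optimize.minimize_scalar(neg2ll, bounds=(lo, hi), method="bounded",
                                   options={"xatol": 1e-10})
    common = sign * math.exp(res.x)
    lr = max(float(res.fun), 0.0)
    df = len(groups) - 1
    p = float(stats.chi2.sf(lr, df))
    return CommonSlopeTest(
        lr_stat=lr, df=df, p_value=p, common_slope=float(common),
        group_slopes=tuple(float(s) for s in slopes),
    )
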