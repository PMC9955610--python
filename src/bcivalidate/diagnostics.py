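"""Statistical test battery for condition-index validation.

Assumption tests for the residual-based indices — linearity (Ramsey's
RESET), homoscedasticity (Breusch–Pagan, studentized Koenker variant),
normality of residuals (Shapiro–Wilk), with D'Agostino's skewness and
the Anscombe–Glynn kurtosis tests to characterize any departure — plus
the nonparametric tools used throughout the validation: Kendall's τ-b
rank correlation and the Mann–Whitney U comparison. Each wrapper
returns a uniform :class:`TestResult` (statistic, df, two-sided p, n)
and enforces the sample-size floor below which its approximation is
not trustworthy.
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.diagnostic import het_breuschpagan, linear_reset

from .datatypes import DegenerateInputError, TestResult
from .regression import fit_ma, fit_ols, fit_sma

__all__ = [
    "reset_test",
    "breusch_pagan",
    "shapiro_wilk",
    "dagostino_skewness",
    "anscombe_glynn_kurtosis",
    "kendall_tau",
    "mann_whitney_u",
    "assumption_battery",
]


def _xy(x, y, min_n):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise DegenerateInputError("x and y must be 1-d arrays of equal length")
    if len(x) < min_n:
        raise DegenerateInputError(f"need at least {min_n} observations, got {len(x)}")
    return x, y


def reset_test(x, y) -> TestResult:
    """Ramsey's RESET test of linearity of E[y | x].

    Augments the OLS fit of y on x with squared and cubed fitted
    values; F-test of the two added terms on (2, n − 4) df.
    """
    x, y = _xy(x, y, 10)
    n = len(x)
    res = sm.OLS(y, sm.add_constant(x)).fit()
    if res.ssr <= 1e-12 * float(np.var(y)) * n:
        raise DegenerateInputError("residual variance is zero; RESET undefined")
    out = linear_reset(res, power=[2, 3], test_type="fitted", use_f=True)
    return TestResult(
        name="reset", statistic=float(out.fvalue), df=(2, n - 4),
        p_value=float(out.pvalue), n=n,
    )


def breusch_pagan(x, y) -> TestResult:
    """Breusch–Pagan test of homoscedasticity (studentized variant).

    Regresses squared OLS residuals on x; LM = n·r² of that auxiliary
    regression, referred to χ² with 1 df.
    """
    x, y = _xy(x, y, 10)
    n = len(x)
    exog = sm.add_constant(x)
    res = sm.OLS(y, exog).fit()
    if res.ssr <= 1e-12 * float(np.var(y)) * n:
        raise DegenerateInputError("residual variance is zero; Breusch-Pagan undefined")
    lm, lm_p, _, _ = het_breuschpagan(res.resid, exog, robust=True)
    return TestResult(name="breusch_pagan", statistic=float(lm), df=1,
                      p_value=float(lm_p), n=n)


def shapiro_wilk(v) -> TestResult:
    """Shapiro–Wilk W test of normality; valid for 3 ≤ n ≤ 5000."""
    v = np.asarray(v, dtype=float)
    n = len(v)
    if not (3 <= n <= 5000):
        raise DegenerateInputError("Shapiro-Wilk requires 3 <= n <= 5000")
    if np.ptp(v) == 0:
        raise DegenerateInputError("constant sample; Shapiro-Wilk undefined")
    w, p = stats.shapiro(v)
    return TestResult(name="shapiro_wilk", statistic=float(w), df=None,
                      p_value=float(p), n=n)


def dagostino_skewness(v) -> TestResult:
    """D'Agostino's skewness test: g1 transformed to ~N(0,1), two-sided."""
    v = np.asarray(v, dtype=float)
    n = len(v)
    if n < 9:
        raise DegenerateInputError("skewness test requires n >= 9")
    z, p = stats.skewtest(v)
    return TestResult(name="dagostino_skewness", statistic=float(z), df=None,
                      p_value=float(p), n=n)


def anscombe_glynn_kurtosis(v) -> TestResult:
    """Anscombe–Glynn kurtosis test: g2 transformed to ~N(0,1), two-sided."""
    v = np.asarray(v, dtype=float)
    n = len(v)
    if n < 20:
        raise DegenerateInputError("kurtosis test requires n >= 20")
    z, p = stats.kurtosistest(v)
    return TestResult(name="anscombe_glynn_kurtosis", statistic=float(z), df=None,
                      p_value=float(p), n=n)


def kendall_tau(x, y) -> TestResult:
    """Kendall's τ-b with tie correction.

    Exact p by enumeration over ranks when n ≤ 8 and both variables
    are tie-free, otherwise the tie-adjusted normal approximation.
    """
    x, y = _xy(x, y, 2)
    n = len(x)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateInputError("all-tied variable; Kendall tau undefined")
    tie_free = len(np.unique(x)) == n and len(np.unique(y)) == n
    method = "exact" if (tie_free and n <= 8) else "asymptotic"
    tau, p = stats.kendalltau(x, y, method=method)
    return TestResult(name="kendall_tau", statistic=float(tau), df=None,
                      p_value=float(p), n=n,
                      note="exact" if method == "exact" else "normal approximation")


def mann_whitney_u(a, b) -> TestResult:
    """Mann–Whitney U two-sample location test, two-sided.

    Exact p when both samples have n ≤ 8 and there are no ties,
    otherwise the normal approximation with continuity and tie
    corrections. The statistic reported is U of the first sample.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise DegenerateInputError("both samples must be nonempty")
    tie_free = len(np.unique(np.concatenate([a, b]))) == len(a) + len(b)
    method = "exact" if (tie_free and len(a) <= 8 and len(b) <= 8) else "asymptotic"
    u, p = stats.mannwhitneyu(a, b, alternative="two-sided", method=method,
                              use_continuity=True)
    return TestResult(name="mann_whitney_u", statistic=float(u), df=None,
                      p_value=float(p), n=len(a) + len(b),
                      note="exact" if method == "exact" else "normal approximation")


# ---------------------------------------------------------------------------
# Assumption battery
# ---------------------------------------------------------------------------

_REGRESSIONS = (
    ("OLSres", "OLS(logM~logL)"),
    ("MAres", "MA(logM~logL)"),
    ("SMAres", "SMA(logM~logL)"),
    ("res(M~L3)", "SMA(M~L3)"),
)

_MIN_GROUP_N = 20


def assumption_battery(records: Sequence, grouping: str = "all",
                       alpha: float = 0.05) -> pd.DataFrame:
    """Assumption tests for every residual-based index, per group.

    For each of the four regressions — OLS, MA and SMA of ln M on
    ln L, and SMA of M on L³ — and each analysis group, the table
    reports RESET and Breusch–Pagan p-values (computable only for the
    vertical-error regressions: the OLS row, and the cubed-length pair
    via its OLS counterpart; MA/SMA ln–ln rows carry NaN, matching the
    dashes of a conventional report), the Shapiro–Wilk p on residuals,
    and the skewness/kurtosis p-values (always computed; flagged
    ``conditional`` because they are conventionally consulted only
    when normality is rejected). The SMA ln–ln rows also carry the
    Fulton slope check: whether the 95% CI of the SMA slope contains
    the isometric value 3.0.

    Under ``by_size_class`` grouping the battery covers the pooled
    data plus each class; groups below n = 20 are skipped with a
    warning.
    """
    if grouping not in ("all", "by_size_class"):
        raise DegenerateInputError("grouping must be 'all' or 'by_size_class'")
    svl = np.array([r.svl_cm for r in records])
    mass = np.array([r.mass_g for r in records])

    groups = [("all", np.ones(len(records), dtype=bool))]
    if grouping == "by_size_class":
        classes = [r.size_class for r in records]
        if any(c is None for c in classes):
            raise DegenerateInputError("size classes must be assigned before grouping")
        for g in sorted(set(classes)):
            groups.append((g, np.array([c == g for c in classes])))

    rows = []
    for gname, sel in groups:
        n = int(sel.sum())
        if n < _MIN_GROUP_N:
            warnings.warn(f"group {gname!r} has n={n} < {_MIN_GROUP_N}; skipped",
                          stacklevel=2)
            continue
        ln_l, ln_m = np.log(svl[sel]), np.log(mass[sel])
        l3, m = svl[sel] ** 3, mass[sel]
        fits = {
            "OLSres": fit_ols(ln_l, ln_m),
            "MAres": fit_ma(ln_l, ln_m),
            "SMAres": fit_sma(ln_l, ln_m),
            "res(M~L3)": fit_sma(l3, m),
        }
        pairs = {"OLSres": (ln_l, ln_m), "res(M~L3)": (l3, m)}
        for bci, regression in _REGRESSIONS:
            fit = fits[bci]
            resid = fit.residuals
            if bci in pairs:
                px, py = pairs[bci]
                reset_p = reset_test(px, py).p_value
                bp_p = breusch_pagan(px, py).p_value
            else:
                reset_p = np.nan
                bp_p = np.nan
            sw_p = shapiro_wilk(resid).p_value
            sk_p = dagostino_skewness(resid).p_value
            ku_p = anscombe_glynn_kurtosis(resid).p_value
            row = {
                "group": gname,
                "bci": bci,
                "regression": regression,
                "n": n,
                "reset_p": reset_p,
                "breusch_pagan_p": bp_p,
                "shapiro_p": sw_p,
                "normality_rejected": sw_p < alpha,
                "skewness_p": sk_p,
                "kurtosis_p": ku_p,
                "skew_kurtosis_conditional": not (sw_p < alpha),
                "fulton_slope": np.nan,
                "fulton_ci_lo": np.nan,
                "fulton_ci_hi": np.nan,
                "fulton_slope_ok": np.nan,
            }
            if bci == "SMAres":
                lo, hi = fit.slope_ci
                row.update(
                    fulton_slope=fit.slope, fulton_ci_lo=lo, fulton_ci_hi=hi,
                    fulton_slope_ok=bool(lo <= 3.0 <= hi),
                )
            rows.append(row)
    return pd.DataFrame(rows)
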