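"""Broken-line (segmented) regression of body mass on length.

A single allometric curve often under- or over-predicts mass at the
extremes of a wide length range. To define size classes that relate
near-isometrically, the mean mass is modelled as a continuous
piecewise-linear function of SVL on the link scale of a GLM, with the
breakpoint locations ψ estimated by iterative linearization (Muggeo's
method): the design is augmented with hinge terms (x − ψ)₊ and
indicator terms, refit, and ψ updated by γ̂/β̂ until the breakpoints
stop moving. The number of breakpoints is chosen by minimum BIC over
k = 0..k_max, where k = 0 is the plain GLM.

Two families are exposed: ``gaussian_identity`` (mean linear in SVL)
and ``gamma_neg_inverse`` (η = −1/μ linear in SVL; the negative sign
keeps the predictor increasing in the mean), the latter matching the
common choice for strictly positive, right-skewed masses.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .datatypes import DegenerateInputError, LineFit, MorphometricRecord, SegmentedModel

__all__ = [
    "FAMILIES",
    "fit_glm",
    "fit_segmented",
    "select_breakpoints",
    "assign_size_classes",
    "binned_mass_table",
    "compare_models_plot",
]

FAMILIES = ("gaussian_identity", "gamma_neg_inverse")


@dataclass
class GlmFit:
    """A fitted GLM: coefficients, covariance, ML log-likelihood."""

    family: str
    coefficients: np.ndarray
    cov: np.ndarray
    fitted: np.ndarray
    loglik: float
    dispersion: float
    converged: bool
    n_iter: int


def _check_family(family: str) -> None:
    if family not in FAMILIES:
        raise DegenerateInputError(f"unknown family {family!r}; choose from {FAMILIES}")


def _gamma_loglik(y: np.ndarray, mu: np.ndarray) -> tuple:
    """Profile the gamma shape out by ML; return (loglik, dispersion).

    dispersion is 1/shape (the squared coefficient of variation).
    """
    n = len(y)
    # ML estimating equation for shape a: n(log a + 1 - digamma(a)) + sum(log(y/mu) - y/mu) = 0
    c = float(np.sum(np.log(y / mu) - y / mu)) / n  # <= -1, equality iff y == mu
    if c >= -1.0 - 1e-12:
        return math.inf, 0.0

    def estfun(log_a):
        a = math.exp(log_a)
        return math.log(a) + 1.0 - special.digamma(a) + c

    lo, hi = -20.0, 30.0
    a = math.exp(optimize.brentq(estfun, lo, hi, xtol=1e-12))
    ll = float(
        np.sum(a * np.log(a * y / mu) - a * y / mu - np.log(y) - special.gammaln(a))
    )
    return ll, 1.0 / a


def fit_glm(X, y, family: str = "gaussian_identity", max_iter: int = 100,
            tol: float = 1e-8) -> GlmFit:
    """Fit a GLM by (iteratively re-)weighted least squares.

    ``X`` is the full design matrix including the intercept column.
    Gaussian/identity solves in one least-squares step; the gamma
    family with negative inverse link (η = −1/μ) iterates IRLS until
    the relative deviance change drops below ``tol``.
    """
    _check_family(family)
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if n <= p:
        raise DegenerateInputError("more parameters than observations")
    if np.linalg.matrix_rank(X) < p:
        raise DegenerateInputError("design matrix is rank deficient")

    if family == "gaussian_identity":
        coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
        fitted = X @ coef
        resid = y - fitted
        ssr = float(resid @ resid)
        sigma2_ml = ssr / n
        loglik = -0.5 * n * (math.log(2.0 * math.pi * sigma2_ml) + 1.0)
        xtx_inv = np.linalg.inv(X.T @ X)
        cov = xtx_inv * (ssr / (n - p))
        return GlmFit(family, coef, cov, fitted, loglik, sigma2_ml, True, 1)

    # gamma with eta = -1/mu
    if np.any(y <= 0):
        raise DegenerateInputError("gamma family requires strictly positive responses")
    mu = np.clip(y, np.percentile(y, 1) * 0.5 + 1e-12, None)
    eta = -1.0 / mu
    dev_old = math.inf
    converged = False
    coef = None
    for it in range(1, max_iter + 1):
        # d(eta)/d(mu) = 1/mu^2 ; gamma variance V(mu) = mu^2
        # IRLS weight w = 1 / (V(mu) * (deta/dmu)^2) = mu^2
        z = eta + (y - mu) / (mu * mu)
        w = mu * mu
        sw = np.sqrt(w)
        coef, _, _, _ = np.linalg.lstsq(X * sw[:, None], z * sw, rcond=None)
        eta = X @ coef
        if np.any(eta >= 0):
            # keep the mean positive; damp towards the previous predictor
            eta = np.minimum(eta, -1e-10)
        mu = -1.0 / eta
        dev = 2.0 * float(np.sum(-np.log(y / mu) + (y - mu) / mu))
        if abs(dev - dev_old) < tol * (abs(dev) + 0.1):
            converged = True
            break
        dev_old = dev
    loglik, dispersion = _gamma_loglik(y, mu)
    w = mu * mu
    xtwx_inv = np.linalg.inv((X * w[:, None]).T @ X)
    cov = xtwx_inv * dispersion
    return GlmFit(family, coef, cov, mu, loglik, dispersion, converged, it)


def _hinge_design(x: np.ndarray, psi: np.ndarray, with_indicators: bool) -> np.ndarray:
    cols = [np.ones_like(x), x]
    for p in psi:
        cols.append(np.clip(x - p, 0.0, None))
    if with_indicators:
        for p in psi:
            cols.append(-(x > p).astype(float))
    return np.column_stack(cols)


def _n_params(k: int) -> int:
    # intercept + base slope + k slope changes + k breakpoints + dispersion
    return 2 * k + 3


def _slope_change_p(Xf: np.ndarray, y: np.ndarray, g: GlmFit, family: str) -> np.ndarray:
    """Two-sided Wald p of each slope-change coefficient.

    Under the gaussian family a heteroscedasticity-robust (HC1
    sandwich) covariance is used, so a slope change supported only by
    high-variance stretches of the data is not declared significant;
    the gamma family's model covariance already scales the variance
    with the squared mean. Because each breakpoint location is itself
    estimated (a nuisance parameter absent under the no-change null),
    the squared Wald statistic is referred to χ² with 2 degrees of
    freedom rather than 1, which keeps the test close to nominal under
    a straight-line null.
    """
    k = Xf.shape[1] - 2
    if k == 0:
        return np.empty(0)
    if family == "gaussian_identity":
        resid = y - Xf @ g.coefficients
        n, p = Xf.shape
        xtxi = np.linalg.inv(Xf.T @ Xf)
        meat = (Xf * (resid**2)[:, None]).T @ Xf * (n / (n - p))
        cov = xtxi @ meat @ xtxi
    else:
        cov = g.cov
    se = np.sqrt(np.maximum(np.diag(cov)[2:], 1e-300))
    z = g.coefficients[2:] / se
    return stats.chi2.sf(z * z, 2)


def fit_segmented(svl, mass, k: int, family: str = "gaussian_identity",
                  psi0=None, max_iter: int = 50, tol: float = 1e-4) -> SegmentedModel:
    """Fit a k-breakpoint broken-line GLM of mass on SVL.

    Breakpoints start at the k interior quantiles (or ``psi0``) and are
    updated by the linearization step ψ ← ψ + γ̂/β̂ until the largest
    move is below ``tol`` cm. If a breakpoint escapes the data range
    the fit is restarted once from perturbed quantiles; failing that, a
    flagged non-converged model is returned. Breakpoint standard
    errors come from the delta method on the final linearized fit.
    """
    _check_family(family)
    x = np.asarray(svl, dtype=float)
    y = np.asarray(mass, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise DegenerateInputError("svl and mass must be 1-d arrays of equal length")
    n = len(x)
    if k < 0:
        raise DegenerateInputError("k must be >= 0")
    if n < 10 * (k + 1):
        raise DegenerateInputError(f"need n >= {10 * (k + 1)} observations for k={k}")

    if k == 0:
        X = np.column_stack([np.ones_like(x), x])
        g = fit_glm(X, y, family)
        bic = -2.0 * g.loglik + _n_params(0) * math.log(n)
        return SegmentedModel(
            family=family, k=0, psi=np.empty(0), psi_se=np.empty(0),
            coefficients=g.coefficients, loglik=g.loglik, bic=bic,
            converged=g.converged, n_iter=g.n_iter, n=n, dispersion=g.dispersion,
        )

    xmin, xmax = float(x.min()), float(x.max())
    span = xmax - xmin
    margin = 0.02 * span
    min_sep = 0.01 * span

    def quantile_init(rng=None):
        qs = np.linspace(0, 1, k + 2)[1:-1]
        init = np.quantile(x, qs)
        if rng is not None:
            init = init + rng.uniform(-0.1 * span / (k + 1), 0.1 * span / (k + 1), k)
        return np.sort(np.clip(init, xmin + margin, xmax - margin))

    def valid(psi):
        return (
            psi[0] > xmin + margin / 2
            and psi[-1] < xmax - margin / 2
            and np.all(np.diff(psi) > min_sep)
        )

    def hinge_deviance(psi):
        """Deviance of the segmented model with the breakpoints held fixed."""
        Xh = _hinge_design(x, psi, with_indicators=False)
        g = fit_glm(Xh, y, family)
        if family == "gaussian_identity":
            return float(np.sum((y - g.fitted) ** 2))
        mu = g.fitted
        return 2.0 * float(np.sum(-np.log(y / mu) + (y - mu) / mu))

    attempts = []
    if psi0 is not None:
        attempts.append(np.sort(np.asarray(psi0, dtype=float)))
    attempts.append(quantile_init())
    attempts.append(quantile_init(np.random.default_rng(0)))

    best = None
    for psi_init in attempts:
        psi = psi_init.copy()
        converged = False
        fit_full = None
        n_iter = 0
        ok = True
        try:
            dev = hinge_deviance(psi)
        except DegenerateInputError:
            continue
        for n_iter in range(1, max_iter + 1):
            X = _hinge_design(x, psi, with_indicators=True)
            try:
                fit_full = fit_glm(X, y, family)
            except DegenerateInputError:
                ok = False
                break
            beta = fit_full.coefficients[2 : 2 + k]
            gamma = fit_full.coefficients[2 + k :]
            if np.any(np.abs(beta) < 1e-12):
                ok = False
                break
            step = gamma / beta
            # step-halving: keep the proposal inside the data range and do
            # not let the segmented deviance deteriorate
            new_psi = None
            new_dev = None
            for _ in range(7):
                cand = np.sort(psi + step)
                if valid(cand):
                    try:
                        cand_dev = hinge_deviance(cand)
                    except DegenerateInputError:
                        cand_dev = math.inf
                    if cand_dev <= dev * (1.0 + 1e-12) + 1e-12:
                        new_psi, new_dev = cand, cand_dev
                        break
                step = step / 2.0
            if new_psi is None:
                # no acceptable move: the objective is stationary here
                converged = True
                break
            moved = float(np.max(np.abs(new_psi - psi)))
            dev_change = abs(dev - new_dev) / (abs(dev) + 1e-12)
            psi, dev = new_psi, new_dev
            if moved < tol or dev_change < 1e-10:
                converged = True
                break
        if not ok or fit_full is None:
            continue
        # final coefficients from the hinge-only design at the converged psi
        Xf = _hinge_design(x, psi, with_indicators=False)
        try:
            g = fit_glm(Xf, y, family)
        except DegenerateInputError:
            continue
        beta = fit_full.coefficients[2 : 2 + k]
        var_gamma = np.diag(fit_full.cov)[2 + k :]
        psi_se = np.sqrt(np.maximum(var_gamma, 0.0)) / np.abs(beta)
        bic = -2.0 * g.loglik + _n_params(k) * math.log(n)
        slope_p = _slope_change_p(Xf, y, g, family)
        model = SegmentedModel(
            family=family, k=k, psi=psi, psi_se=psi_se,
            coefficients=g.coefficients, loglik=g.loglik, bic=bic,
            converged=converged, n_iter=n_iter, n=n, dispersion=g.dispersion,
            slope_change_p=slope_p,
        )
        if converged:
            return model
        if best is None:
            best = model
    if best is not None:
        return best
    # every attempt degenerated: report a flagged, non-converged shell
    return SegmentedModel(
        family=family, k=k, psi=np.full(k, np.nan), psi_se=np.full(k, np.nan),
        coefficients=np.full(k + 2, np.nan), loglik=-math.inf, bic=math.inf,
        converged=False, n_iter=0, n=n,
    )


def select_breakpoints(svl, mass, k_max: int = 10, family: str = "gaussian_identity",
                       guard_alpha: float = 0.05) -> SegmentedModel:
    """Choose the number of breakpoints by minimum BIC over k = 0..k_max.

    A candidate with k ≥ 1 breakpoints is admissible only when every
    slope-change coefficient is significant at the Bonferroni-corrected
    level ``guard_alpha``/k (heteroscedasticity-robust Wald under the
    gaussian family); this guards the BIC comparison against spurious
    breakpoints manufactured from high-variance stretches of the data.
    Pass ``guard_alpha=None`` for pure minimum-BIC selection.
    Non-converged candidates are excluded (NaN in ``bic_trace``);
    exact BIC ties break toward the smaller k. The selected model
    carries the full BIC trace.
    """
    x = np.asarray(svl, dtype=float)
    n = len(x)
    trace = {}
    best = None
    for k in range(0, k_max + 1):
        if n < 10 * (k + 1):
            break
        try:
            m = fit_segmented(svl, mass, k, family=family)
        except DegenerateInputError:
            trace[k] = float("nan")
            continue
        if not m.converged:
            trace[k] = float("nan")
            continue
        trace[k] = m.bic
        if (guard_alpha is not None and k > 0
                and float(np.max(m.slope_change_p)) > guard_alpha / k):
            continue
        if best is None or m.bic < best.bic:
            best = m
    if best is None:
        raise DegenerateInputError("no candidate model converged")
    best.bic_trace = trace
    return best


def assign_size_classes(records, psi) -> list:
    """Label records with 1-based size classes by half-open intervals.

    Class i covers ψ_{i−1} ≤ SVL < ψ_i; the last class covers
    SVL ≥ ψ_last, so a length exactly at a breakpoint belongs to the
    class above it.
    """
    psi = np.sort(np.asarray(psi, dtype=float))
    out = []
    for r in records:
        cls = int(np.searchsorted(psi, r.svl_cm, side="right")) + 1
        out.append(
            MorphometricRecord(
                id=r.id, sex=r.sex, svl_cm=r.svl_cm, mass_g=r.mass_g, fat_g=r.fat_g,
                days_held=r.days_held, flags=r.flags, size_class=cls, extra=r.extra,
            )
        )
    return out


def binned_mass_table(records, bin_width: float = 2.0,
                      svl_range: tuple = (10.0, 46.4)) -> pd.DataFrame:
    """Mean ± SE of mass in fixed-width SVL bins; empty bins omitted."""
    svl = np.array([r.svl_cm for r in records])
    mass = np.array([r.mass_g for r in records])
    lo, hi = svl_range
    edges = np.arange(lo, hi + bin_width, bin_width)
    rows = []
    for a, b in zip(edges[:-1], edges[1:]):
        sel = (svl >= a) & (svl < b)
        m = int(sel.sum())
        if m == 0:
            continue
        vals = mass[sel]
        rows.append(
            {
                "svl_lo": a,
                "svl_hi": b,
                "svl_mid": (a + b) / 2.0,
                "n": m,
                "mean_mass_g": float(vals.mean()),
                "se_mass_g": float(vals.std(ddof=1) / math.sqrt(m)) if m > 1 else float("nan"),
            }
        )
    return pd.DataFrame(rows)


def compare_models_plot(records, basic_fit: LineFit, segmented_model: SegmentedModel,
                        bin_width: float = 2.0, svl_range: tuple = (10.0, 46.4),
                        ax=None):
    """Binned mass means overlaid with the allometric and segmented curves.

    ``basic_fit`` is the ln–ln allometric line (mass predicted as
    exp(a + b ln L)). Returns (table, matplotlib Axes).
    """
    table = binned_mass_table(records, bin_width=bin_width, svl_range=svl_range)
    if ax is None:
        import matplotlib

        matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt

        _, ax = plt.subplots(figsize=(7, 5))
    svl = np.array([r.svl_cm for r in records])
    grid = np.linspace(svl.min(), svl.max(), 300)
    ax.errorbar(table["svl_mid"], table["mean_mass_g"], yerr=table["se_mass_g"],
                fmt="o", color="black", capsize=2, label=f"{bin_width:g} cm bin means")
    ax.plot(grid, np.exp(basic_fit.predict(np.log(grid))), "-", color="tab:blue",
            label="allometric model")
    ax.plot(grid, segmented_model.predict_mean(grid), "-", color="tab:red",
            label=f"segmented model (k={segmented_model.k})")
    ax.set_xlabel("SVL (cm)")
    ax.set_ylabel("body mass (g)")
    ax.legend()
    return table, ax
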