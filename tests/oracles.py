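"""Independent brute-force oracles used to cross-check the fast paths.

These deliberately avoid the closed-form estimators in the package:
line fits are found by direct numerical minimization of each method's
loss, and the rank-test p-values by exhaustive enumeration.
"""

from itertools import combinations, permutations

import numpy as np
from scipy import optimize


def _minimize_line(loss, x, y):
    """Minimize loss(a, b) over intercept/slope with multiple starts."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    b0 = np.polyfit(x, y, 1)[0]
    best = None
    for b_start in (b0, 2.0 * b0, 0.5 * b0):
        a_start = y.mean() - b_start * x.mean()
        res = optimize.minimize(
            lambda p: loss(p[0], p[1], x, y), [a_start, b_start],
            method="Nelder-Mead",
            options={"xatol": 1e-12, "fatol": 1e-14, "maxiter": 20000, "maxfev": 20000},
        )
        if best is None or res.fun < best.fun:
            best = res
    return best.x  # (a, b)


def brute_ols(x, y):
    """Minimize vertical squared deviations."""
    return _minimize_line(lambda a, b, x, y: np.sum((y - a - b * x) ** 2), x, y)


def brute_ma(x, y):
    """Minimize orthogonal squared deviations."""
    return _minimize_line(
        lambda a, b, x, y: np.sum((y - a - b * x) ** 2) / (1.0 + b * b), x, y
    )


def brute_sma(x, y):
    """Minimize summed triangle areas |dx · dy| / 2.

    For a point at vertical distance r from the line with slope b, the
    triangle between the point and the line has area r²/(2|b|), so the
    loss is Σ (y − a − b x)² / |b|.
    """
    return _minimize_line(
        lambda a, b, x, y: np.sum((y - a - b * x) ** 2) / max(abs(b), 1e-12), x, y
    )


def exact_kendall_p(x, y):
    """Two-sided Kendall p by enumerating all n! orderings (n ≤ 8, no ties)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = len(x)
    assert n <= 8

    def s_stat(yy):
        s = 0
        for i in range(n):
            for j in range(i + 1, n):
                s += np.sign(x[j] - x[i]) * np.sign(yy[j] - yy[i])
        return s

    obs = abs(s_stat(y))
    hits = total = 0
    for perm in permutations(y):
        total += 1
        if abs(s_stat(np.asarray(perm))) >= obs - 1e-12:
            hits += 1
    return hits / total


def exact_mannwhitney_p(a, b):
    """Two-sided Mann–Whitney p by enumerating all group labelings."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    pooled = np.concatenate([a, b])
    n1, n = len(a), len(pooled)

    def u_of(idx):
        idx = set(idx)
        aa = pooled[list(idx)]
        bb = pooled[[i for i in range(n) if i not in idx]]
        return float(sum((xa > xb) + 0.5 * (xa == xb) for xa in aa for xb in bb))

    mu = n1 * (n - n1) / 2.0
    obs = abs(u_of(range(n1)) - mu)
    hits = total = 0
    for idx in combinations(range(n), n1):
        total += 1
        if abs(u_of(idx) - mu) >= obs - 1e-12:
            hits += 1
    return hits / total
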