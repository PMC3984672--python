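"""Shared statistical helpers: exact binomial intervals, trimmed proportional
fits, and exact-permutation Spearman tests."""

from __future__ import annotations

import itertools

import numpy as np
from scipy import stats


def clopper_pearson(k: int, n: int, alpha: float = 0.05) -> tuple[float, float]:
    """Exact two-sided binomial confidence interval for k successes in n trials.

    Obtained by inverting binomial tail probabilities (beta-quantile form).
    Returns (lower, upper) on the proportion scale.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if not 0 <= k <= n:
        raise ValueError("k must lie in [0, n]")
    lo = 0.0 if k == 0 else float(stats.beta.ppf(alpha / 2, k, n - k + 1))
    hi = 1.0 if k == n else float(stats.beta.ppf(1 - alpha / 2, k + 1, n - k))
    return lo, hi


def trimmed_proportional_fit(x, y, trim: float = 0.05):
    """Zero-intercept least-squares slope of y on x over the central ratio band.

    Samples are ranked by y/x; those between the `trim` and `1-trim` quantiles
    (inclusive) are retained and the slope sum(x*y)/sum(x*x) is fitted on them.
    The trim is on the ratio distribution, so a few extreme outliers cannot
    drag the fitted proportionality constant.

    Returns (slope, kept_mask).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-d arrays")
    if np.any(x <= 0):
        raise ValueError("x must be strictly positive for ratio trimming")
    ratio = y / x
    lo, hi = np.percentile(ratio, [100 * trim, 100 * (1 - trim)])
    kept = (ratio >= lo) & (ratio <= hi)
    if kept.sum() < 2:
        raise ValueError("fewer than 2 samples retained after trimming")
    xk, yk = x[kept], y[kept]
    slope = float(np.dot(xk, yk) / np.dot(xk, xk))
    return slope, kept


def _rank(a: np.ndarray) -> np.ndarray:
    return stats.rankdata(a)


def spearman_exact_p(x, y) -> float:
    """Two-sided exact permutation p-value for the Spearman correlation.

    Enumerates all pairings of the rank vectors (chunked so memory stays
    bounded). Intended for small n; the caller switches to the t-approximation
    above n = 10.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    rx, ry = _rank(x), _rank(y)
    sx, sy = rx.std(), ry.std()
    if sx == 0 or sy == 0:
        raise ValueError("constant input vector")
    obs = abs(np.corrcoef(rx, ry)[0, 1])
    mx = rx.mean()
    count = 0
    total = 0
    chunk = []
    denom = n * sx * sy

    def flush(chunk):
        perms = np.array(chunk)
        # corr of rx with each permuted ry, vectorised via dot products
        dots = perms @ rx
        rhos = (dots - n * mx * ry.mean()) / denom
        return int(np.sum(np.abs(rhos) >= obs - 1e-12)), len(chunk)

    for perm in itertools.permutations(ry):
        chunk.append(perm)
        if len(chunk) == 100_000:
            c, t = flush(chunk)
            count += c
            total += t
            chunk = []
    if chunk:
        c, t = flush(chunk)
        count += c
        total += t
    return count / total


def fraction_rsquared(x, y) -> float:
    """Coefficient of determination of the OLS line of y on x."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3:
        raise ValueError("need at least 3 points")
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0:
        return 1.0
    return 1.0 - ss_res / ss_tot
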