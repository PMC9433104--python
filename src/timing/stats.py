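"""Nonparametric statistics shared across the package.

Implements the small battery of rank-based tests used throughout the
analysis — Mann-Whitney U (exact enumeration for small tie-free samples,
normal approximation otherwise), Kruskal-Wallis, Pearson/Spearman
correlation with two-sided p-values, and Benjamini-Hochberg FDR — with
explicit, documented conventions (midranks for ties, continuity
correction, step-up q-values with monotone enforcement).

These are implemented here rather than delegated so that the exact
small-sample branch and tie handling are fully specified; scipy is used
only for reference distributions (normal, chi-square, t).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as _spstats

__all__ = [
    "TestResult",
    "mann_whitney_u",
    "kruskal_wallis",
    "correlation",
    "bh_fdr",
]

#: combined sample size at or below which the exact Mann-Whitney null
#: distribution is enumerated (tie-free data only)
EXACT_N_MAX = 12


@dataclass
class TestResult:
    """Outcome of a two-sided hypothesis test."""

    statistic: float
    p_two_sided: float
    method: str
    n: tuple = ()
    flags: list = field(default_factory=list)


def _rankdata(values: np.ndarray) -> np.ndarray:
    """Midranks (average ranks for ties), 1-based."""
    return _spstats.rankdata(values, method="average")


def _tie_term(values: np.ndarray) -> float:
    """sum over tie groups of t^3 - t."""
    _, counts = np.unique(values, return_counts=True)
    return float(np.sum(counts.astype(float) ** 3 - counts))


def _exact_u_counts(nx: int, ny: int) -> np.ndarray:
    """Exact null counts of U for sample sizes (nx, ny), no ties."""
    # f[m][u]: number of ways to choose which of the first (m+n) ranks are
    # x's such that U == u.  Recursion on the largest rank.
    max_u = nx * ny
    # table indexed by current nx value
    f = [np.zeros(max_u + 1) for _ in range(nx + 1)]
    f[0][0] = 1.0
    for m in range(1, nx + ny + 1):
        # process ranks 1..m; iterate nx downward so each rank used once
        for k in range(min(nx, m), 0, -1):
            # assigning rank m to an x adds (number of y's among ranks < m)
            # = (m - k) to U
            add = m - k
            if add > max_u:
                continue
            src = f[k - 1]
            dst = f[k]
            dst[add:] += src[: max_u + 1 - add]
    return f[nx]


def mann_whitney_u(x, y, exact_n_max: int = EXACT_N_MAX) -> TestResult:
    """Two-sided Mann-Whitney U test.

    Uses exact enumeration of the null distribution when the combined
    sample size is <= ``exact_n_max`` and the data are tie-free; otherwise
    the normal approximation with tie and continuity corrections.

    Returns the U statistic for ``x`` (number of (x, y) pairs with
    x > y, counting ties as 1/2).
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size == 0 or y.size == 0:
        raise ValueError("mann_whitney_u requires two non-empty samples")
    nx, ny = x.size, y.size
    combined = np.concatenate([x, y])
    ranks = _rankdata(combined)
    rx = float(ranks[:nx].sum())
    u = rx - nx * (nx + 1) / 2.0

    has_ties = np.unique(combined).size < combined.size
    if nx + ny <= exact_n_max and not has_ties:
        counts = _exact_u_counts(nx, ny)
        total = counts.sum()
        ui = int(round(u))
        p_le = counts[: ui + 1].sum() / total
        p_ge = counts[ui:].sum() / total
        p = min(1.0, 2.0 * min(p_le, p_ge))
        return TestResult(u, p, "exact", (nx, ny))

    mu = nx * ny / 2.0
    n = nx + ny
    tie = _tie_term(combined)
    var = nx * ny / 12.0 * ((n + 1) - tie / (n * (n - 1)))
    flags = []
    if var <= 0:
        # all values identical: no evidence either way
        return TestResult(u, 1.0, "normal_approx", (nx, ny), ["degenerate"])
    z = (abs(u - mu) - 0.5) / np.sqrt(var)
    z = max(z, 0.0)
    p = min(1.0, 2.0 * _spstats.norm.sf(z))
    return TestResult(u, p, "normal_approx", (nx, ny), flags)


def kruskal_wallis(groups) -> TestResult:
    """Kruskal-Wallis H test across >= 2 groups, chi-square p (k-1 df)."""
    groups = [np.asarray(g, dtype=float).ravel() for g in groups]
    if len(groups) < 2 or any(g.size == 0 for g in groups):
        raise ValueError("kruskal_wallis requires >= 2 non-empty groups")
    sizes = [g.size for g in groups]
    combined = np.concatenate(groups)
    n = combined.size
    ranks = _rankdata(combined)
    h = 0.0
    start = 0
    for sz in sizes:
        rsum = ranks[start : start + sz].sum()
        h += rsum**2 / sz
        start += sz
    h = 12.0 / (n * (n + 1)) * h - 3.0 * (n + 1)
    correction = 1.0 - _tie_term(combined) / (n**3 - n)
    if correction <= 0:
        return TestResult(0.0, 1.0, "kruskal_wallis", tuple(sizes), ["degenerate"])
    h /= correction
    p = float(_spstats.chi2.sf(h, len(groups) - 1))
    return TestResult(h, min(1.0, p), "kruskal_wallis", tuple(sizes))


def correlation(x, y, method: str = "pearson") -> TestResult:
    """Correlation coefficient with a two-sided t-approximation p-value.

    ``method`` is "pearson" or "spearman" (Pearson on midranks).  A
    zero-variance input yields a NaN coefficient with a "degenerate" flag.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size or x.size < 3:
        raise ValueError("correlation requires equal-length inputs with n >= 3")
    if method == "spearman":
        x, y = _rankdata(x), _rankdata(y)
    elif method != "pearson":
        raise ValueError(f"unknown correlation method: {method!r}")
    if np.std(x) == 0 or np.std(y) == 0:
        return TestResult(float("nan"), float("nan"), method, (x.size,), ["degenerate"])
    r = float(np.corrcoef(x, y)[0, 1])
    n = x.size
    r_clip = min(max(r, -1.0), 1.0)
    if abs(r_clip) == 1.0:
        p = 0.0
    else:
        t = r_clip * np.sqrt((n - 2) / (1.0 - r_clip**2))
        p = float(2.0 * _spstats.t.sf(abs(t), n - 2))
    return TestResult(r, min(1.0, p), method, (n,))


def bh_fdr(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values with monotone enforcement.

    q_(k) = min_{i >= k} ( m * p_(i) / i ), clipped to [0, 1].
    """
    p = np.asarray(pvals, dtype=float).ravel()
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    # running minimum from the largest p downwards
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty_like(q_sorted)
    q[order] = q_sorted
    return q
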