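"""Clinical IHC H-score analysis and progression-free-survival stratification.

The H score summarizes chromogenic IHC staining of a biopsy as

    H = %mild * 1 + %moderate * 2 + %intense * 3        (range 0-300)

where the three percentages are the fractions of tumor cells staining at
mild, moderate and intense intensity.  A cohort of patients scored this
way can be dichotomized at an H-score cutoff chosen by ROC analysis
against the clinical response label, and the two strata compared on
progression-free survival (PFS) with Kaplan-Meier curves and a log-rank
test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as _spstats

__all__ = [
    "h_score",
    "roc_cutoff",
    "km_estimate",
    "logrank_test",
    "stratified_pfs",
    "RocResult",
    "SurvivalCurve",
    "StratifiedPFS",
]


def h_score(pct_mild, pct_moderate, pct_intense) -> float:
    """IHC H score: %mild*1 + %moderate*2 + %intense*3 (0-300)."""
    parts = (pct_mild, pct_moderate, pct_intense)
    for p in parts:
        if not np.isfinite(p) or p < 0 or p > 100:
            raise ValueError(f"staining percentage out of [0, 100]: {p}")
    if sum(parts) > 100 + 1e-9:
        raise ValueError("staining percentages sum to more than 100%")
    return float(pct_mild * 1 + pct_moderate * 2 + pct_intense * 3)


@dataclass
class RocResult:
    cutoff: float
    sensitivity: float
    specificity: float
    mode: str
    youden: float = float("nan")


def roc_cutoff(scores, labels, mode: str = "youden", target: float = 0.94) -> RocResult:
    """Choose a score cutoff from a ROC sweep.

    Scores >= cutoff are called positive.  Candidate cutoffs are the
    midpoints between consecutive sorted unique scores (so every achievable
    confusion table is represented).  ``mode="youden"`` maximizes
    sensitivity + specificity - 1; ``mode="target_specificity"`` returns the
    smallest cutoff whose specificity is >= ``target``.  Ties are broken
    toward the lower cutoff.
    """
    scores = np.asarray(scores, dtype=float).ravel()
    labels = np.asarray(labels).astype(bool).ravel()
    if scores.size != labels.size or scores.size == 0:
        raise ValueError("scores and labels must be non-empty and equal length")
    n_pos = int(labels.sum())
    n_neg = int((~labels).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("roc_cutoff requires both classes present")
    uniq = np.unique(scores)
    if uniq.size < 2:
        raise ValueError("all scores identical: no informative cutoff exists")
    candidates = (uniq[:-1] + uniq[1:]) / 2.0

    best = None
    for c in candidates:
        pred = scores >= c
        sens = float((pred & labels).sum()) / n_pos
        spec = float((~pred & ~labels).sum()) / n_neg
        if mode == "youden":
            j = sens + spec - 1.0
            if best is None or j > best.youden + 1e-12:
                best = RocResult(float(c), sens, spec, mode, j)
        elif mode == "target_specificity":
            if spec >= target:
                return RocResult(float(c), sens, spec, mode, sens + spec - 1.0)
        else:
            raise ValueError(f"unknown mode: {mode!r}")
    if mode == "target_specificity":
        raise ValueError(f"no cutoff achieves specificity >= {target}")
    return best


@dataclass
class SurvivalCurve:
    """Kaplan-Meier product-limit estimate.

    ``times`` are the distinct observed times (events or censorings) in
    increasing order; ``survival[i]`` is S(times[i]); ``at_risk[i]`` and
    ``n_events[i]`` describe the risk set at that time.  The median is the
    first time at which S(t) <= 0.5, or NaN if never reached.
    """

    times: np.ndarray
    at_risk: np.ndarray
    n_events: np.ndarray
    survival: np.ndarray
    median: float = float("nan")
    n: int = 0


def km_estimate(times, events) -> SurvivalCurve:
    """Kaplan-Meier estimator S(t) = prod_{t_i <= t} (1 - d_i / n_i)."""
    times = np.asarray(times, dtype=float).ravel()
    events = np.asarray(events).astype(int).ravel()
    if times.size == 0 or times.size != events.size:
        raise ValueError("times and events must be non-empty and equal length")
    if np.any(times < 0) or np.any(~np.isfinite(times)):
        raise ValueError("survival times must be finite and non-negative")

    uniq = np.unique(times)
    at_risk = np.empty(uniq.size)
    d = np.empty(uniq.size)
    surv = np.empty(uniq.size)
    s = 1.0
    for i, t in enumerate(uniq):
        n_i = int((times >= t).sum())
        d_i = int(((times == t) & (events == 1)).sum())
        if n_i > 0 and d_i > 0:
            s *= 1.0 - d_i / n_i
        at_risk[i] = n_i
        d[i] = d_i
        surv[i] = s
    median = float("nan")
    below = np.nonzero(surv <= 0.5 + 1e-12)[0]
    if below.size:
        median = float(uniq[below[0]])
    return SurvivalCurve(uniq, at_risk, d, surv, median, n=int(times.size))


def logrank_test(times_a, events_a, times_b, events_b):
    """Two-group log-rank test (1 df chi-square).

    At each pooled event time, the observed events in group A are compared
    with the expectation under the null of a common hazard, with the usual
    hypergeometric variance.  Returns a :class:`~timing.stats.TestResult`-like
    tuple (chi2, p) wrapped in a small dataclass.
    """
    from .stats import TestResult

    ta = np.asarray(times_a, dtype=float).ravel()
    ea = np.asarray(events_a).astype(int).ravel()
    tb = np.asarray(times_b, dtype=float).ravel()
    eb = np.asarray(events_b).astype(int).ravel()
    if ta.size == 0 or tb.size == 0:
        raise ValueError("both groups must be non-empty")

    all_times = np.concatenate([ta, tb])
    all_events = np.concatenate([ea, eb])
    group = np.concatenate([np.zeros(ta.size, int), np.ones(tb.size, int)])
    event_times = np.unique(all_times[all_events == 1])
    if event_times.size == 0:
        return TestResult(0.0, 1.0, "logrank", (ta.size, tb.size), ["no_events"])

    o_minus_e = 0.0
    var = 0.0
    for t in event_times:
        at_risk = all_times >= t
        n = int(at_risk.sum())
        n_a = int((at_risk & (group == 0)).sum())
        d = int(((all_times == t) & (all_events == 1)).sum())
        d_a = int(((all_times == t) & (all_events == 1) & (group == 0)).sum())
        if n == 0:
            continue
        e_a = d * n_a / n
        o_minus_e += d_a - e_a
        if n > 1:
            var += d * (n_a / n) * (1 - n_a / n) * (n - d) / (n - 1)
    if var <= 0:
        return TestResult(0.0, 1.0, "logrank", (ta.size, tb.size), ["degenerate"])
    chi2 = o_minus_e**2 / var
    p = float(_spstats.chi2.sf(chi2, 1))
    return TestResult(chi2, min(1.0, p), "logrank", (ta.size, tb.size))


@dataclass
class StratifiedPFS:
    """PFS comparison between high and low H-score strata."""

    cutoff: float
    curve_high: SurvivalCurve
    curve_low: SurvivalCurve
    median_high: float
    median_low: float
    logrank_chi2: float
    logrank_p: float
    n_high: int = 0
    n_low: int = 0

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "group": [f"H>={self.cutoff:g}", f"H<{self.cutoff:g}"],
                "n": [self.n_high, self.n_low],
                "median_pfs": [self.median_high, self.median_low],
                "logrank_chi2": [self.logrank_chi2] * 2,
                "logrank_p": [self.logrank_p] * 2,
            }
        )


def stratified_pfs(cohort: pd.DataFrame, cutoff: float = 80.0) -> StratifiedPFS:
    """Stratify a cohort at an H-score cutoff and compare PFS.

    ``cohort`` must carry columns ``h_score``, ``pfs_months`` and ``event``.
    Groups are h_score >= cutoff ("high") versus h_score < cutoff ("low").
    """
    if not 0 <= cutoff <= 300:
        raise ValueError("H-score cutoff must lie in [0, 300]")
    for col in ("h_score", "pfs_months", "event"):
        if col not in cohort.columns:
            raise ValueError(f"cohort is missing required column {col!r}")
    high = cohort[cohort["h_score"] >= cutoff]
    low = cohort[cohort["h_score"] < cutoff]
    if len(high) == 0 or len(low) == 0:
        raise ValueError(
            f"cutoff {cutoff} leaves an empty stratum "
            f"(high n={len(high)}, low n={len(low)})"
        )
    curve_high = km_estimate(high["pfs_months"], high["event"])
    curve_low = km_estimate(low["pfs_months"], low["event"])
    lr = logrank_test(high["pfs_months"], high["event"], low["pfs_months"], low["event"])
    return StratifiedPFS(
        cutoff=float(cutoff),
        curve_high=curve_high,
        curve_low=curve_low,
        median_high=curve_high.median,
        median_low=curve_low.median,
        logrank_chi2=float(lr.statistic),
        logrank_p=float(lr.p_two_sided),
        n_high=len(high),
        n_low=len(low),
    )
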