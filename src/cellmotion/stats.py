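"""Nonparametric group comparisons and median/IQR summaries.

The analyses throughout the pipeline are distribution-free: two-sample
Wilcoxon rank-sum (Mann–Whitney) tests with a reported Z statistic, and
Kruskal–Wallis H tests for more than two groups.  Dispersion is reported as
"median/IQR" strings, the convention used in the per-group result tables.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
from scipy import stats as sps

#: Largest pooled sample for which the rank-sum p-value is computed by full
#: enumeration of rank assignments (only when the pooled data are tie-free).
EXACT_MAX_N = 12


@dataclass(frozen=True)
class TestResult:
    statistic: float      # Z (rank_sum) or H (kruskal_wallis)
    p_value: float
    method: str
    group_sizes: tuple[int, ...]


def _ranksum_z(a: np.ndarray, b: np.ndarray, continuity: bool = True) -> float:
    """Normal-approximation Z with midranks, tie-corrected variance, continuity
    correction; Z > 0 when sample ``a`` tends larger."""
    n1, n2 = len(a), len(b)
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)
    w = ranks[:n1].sum()
    mu = n1 * (n1 + n2 + 1) / 2.0
    n = n1 + n2
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(counts**3 - counts) / ((n) * (n - 1)) if n > 1 else 0.0
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if var <= 0:
        return 0.0
    delta = w - mu
    if continuity:
        delta -= 0.5 * np.sign(delta)
    return float(delta / np.sqrt(var))


def rank_sum(a, b, continuity: bool = True) -> TestResult:
    """Two-sided Wilcoxon rank-sum test of two independent samples.

    For pooled sizes <= 12 with no ties the p-value is exact (full enumeration
    of rank assignments); otherwise the tie-corrected normal approximation
    with continuity correction is used.  The Z statistic is positive when
    ``a`` tends larger than ``b``.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 1 or len(b) < 1:
        raise ValueError("both samples need at least one observation")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        return TestResult(0.0, 1.0, "rank_sum (degenerate)", (len(a), len(b)))
    z = _ranksum_z(a, b, continuity=continuity)
    n1, n2 = len(a), len(b)
    if n1 + n2 <= EXACT_MAX_N and len(np.unique(pooled)) == n1 + n2:
        p = _exact_ranksum_p(a, b)
        method = "rank_sum (exact)"
    else:
        p = float(2.0 * sps.norm.sf(abs(z)))
        method = "rank_sum (normal approx)"
    return TestResult(z, min(p, 1.0), method, (n1, n2))


def _exact_ranksum_p(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided p by enumerating every assignment of ranks to the first sample."""
    n1 = len(a)
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)
    w_obs = ranks[:n1].sum()
    n = len(pooled)
    mu = n1 * (n + 1) / 2.0
    extreme = 0
    for idx in combinations(range(n), n1):
        w = ranks[list(idx)].sum()
        if abs(w - mu) >= abs(w_obs - mu) - 1e-12:
            extreme += 1
    return extreme / comb(n, n1)


def kruskal_wallis(groups) -> TestResult:
    """Kruskal–Wallis H test (tie-corrected) across two or more groups."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    if any(len(g) == 0 for g in groups):
        raise ValueError("all groups must be nonempty")
    pooled = np.concatenate(groups)
    if len(pooled) < 5:
        raise ValueError("need at least 5 observations in total")
    if np.all(pooled == pooled[0]):
        return TestResult(0.0, 1.0, "kruskal_wallis (degenerate)",
                          tuple(len(g) for g in groups))
    h, p = sps.kruskal(*groups)
    return TestResult(float(h), float(p), "kruskal_wallis",
                      tuple(len(g) for g in groups))


def summarize(values) -> dict:
    """Median, IQR (Q3 − Q1, linear-interpolation quantiles), min and max."""
    values = np.asarray(values, dtype=float)
    values = values[np.isfinite(values)]
    if len(values) == 0:
        raise ValueError("cannot summarize an empty sample")
    q1, med, q3 = np.percentile(values, [25, 50, 75])
    return {
        "median": float(med),
        "iqr": float(q3 - q1),
        "min": float(values.min()),
        "max": float(values.max()),
        "n": int(len(values)),
    }


def median_iqr_string(values, fmt: str = "{:.2f}") -> str:
    """'median/IQR' formatted summary, e.g. ``0.72/0.08``."""
    s = summarize(values)
    return f"{fmt.format(s['median'])}/{fmt.format(s['iqr'])}"
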