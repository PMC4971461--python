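"""Nonparametric group comparison of cross-validated OPLS scores.

The per-muscle group difference is tested with the two-sided
Mann-Whitney-Wilcoxon test on the leave-one-out cross-validated predictive
scores; p <= alpha (default 0.05) flags a muscle as significant.  The exact
null distribution is used for small untied samples (n1*n2 <= 400), else the
normal approximation with tie and continuity corrections.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

EXACT_LIMIT = 400  # full enumeration is cheap up to n1*n2 = 400


@dataclass
class TestResult:
    u_statistic: float
    p_value: float
    method: str            # "exact" | "normal-approximation"
    significant: bool
    alpha: float = 0.05


def mann_whitney(scores: np.ndarray, labels: np.ndarray,
                 alpha: float = 0.05) -> TestResult:
    """Two-sided Mann-Whitney U test of group-1 vs group-0 scores.

    U is reported for the group-1 sample (range [0, n1*n2]).  With every
    value tied the statistic is its null mean n1*n2/2 and p = 1.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    g1 = scores[labels == 1]
    g0 = scores[labels == 0]
    if g1.size == 0 or g0.size == 0:
        raise ValueError("both groups must be non-empty")

    n1, n0 = g1.size, g0.size
    if np.ptp(scores) == 0:
        return TestResult(u_statistic=n1 * n0 / 2.0, p_value=1.0,
                          method="normal-approximation",
                          significant=1.0 <= alpha, alpha=alpha)

    has_ties = np.unique(scores).size < scores.size
    if n1 * n0 <= EXACT_LIMIT and not has_ties:
        method = "exact"
        res = stats.mannwhitneyu(g1, g0, alternative="two-sided",
                                 method="exact")
    else:
        method = "normal-approximation"
        res = stats.mannwhitneyu(g1, g0, alternative="two-sided",
                                 method="asymptotic", use_continuity=True)
    p = float(min(res.pvalue, 1.0))
    return TestResult(u_statistic=float(res.statistic), p_value=p,
                      method=method, significant=p <= alpha, alpha=alpha)


def summarize_muscles(results: dict[str, TestResult],
                      alpha: float = 0.05) -> pd.DataFrame:
    """Per-muscle significance table (one row per muscle)."""
    if not results:
        raise ValueError("need at least one muscle result")
    rows = [
        {
            "muscle": muscle,
            "U": r.u_statistic,
            "p_value": r.p_value,
            "method": r.method,
            "significant": r.p_value <= alpha,
        }
        for muscle, r in results.items()
    ]
    return pd.DataFrame(rows)
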