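"""Frequentist utilities: equal-proportion test, Fisher's exact test,
Wilcoxon rank-sum and rank-based AUC.

The two-sample proportion test follows the R ``prop.test`` convention
(Yates-corrected Pearson chi-square, Wald confidence interval with a
continuity term), which is the convention under which the cohort-level
colitis-by-therapy comparisons were originally reported.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy import stats

__all__ = ["PropTestResult", "prop_test", "fisher_exact", "wilcoxon_rank_sum", "auc_rank"]


@dataclass(frozen=True)
class PropTestResult:
    delta: float
    ci_low: float
    ci_high: float
    chi2: float
    p: float


def prop_test(
    x1: int,
    n1: int,
    x2: int,
    n2: int,
    conf: float = 0.95,
    continuity: bool = True,
) -> PropTestResult:
    """Two-sided test of equal proportions for two groups.

    ``delta`` is ``x2/n2 - x1/n1`` (second group minus first).  The
    chi-square statistic is the Pearson statistic on the 2x2 table with
    Yates continuity correction (clamped so the corrected deviation cannot
    change sign); the confidence interval is the Wald interval widened by
    the continuity term ``(1/n1 + 1/n2)/2`` and clamped to [-1, 1].
    """
    for x, n in ((x1, n1), (x2, n2)):
        if n <= 0 or not 0 <= x <= n:
            raise ValueError("counts must satisfy 0 <= successes <= total, total > 0")
    table = np.array([[x1, n1 - x1], [x2, n2 - x2]], dtype=float)
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValueError("degenerate 2x2 table: a margin is zero")

    expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / table.sum()
    dev = np.abs(table - expected)
    if continuity:
        dev = np.maximum(dev - 0.5, 0.0)
    chi2 = float((dev**2 / expected).sum())
    p = float(stats.chi2.sf(chi2, df=1))

    p1, p2 = x1 / n1, x2 / n2
    delta = p2 - p1
    z = stats.norm.ppf((1 + conf) / 2)
    half = z * np.sqrt(p1 * (1 - p1) / n1 + p2 * (1 - p2) / n2)
    if continuity:
        half += (1 / n1 + 1 / n2) / 2
    ci_low = max(delta - half, -1.0)
    ci_high = min(delta + half, 1.0)
    return PropTestResult(delta=delta, ci_low=ci_low, ci_high=ci_high, chi2=chi2, p=p)


def fisher_exact(x1: int, n1: int, x2: int, n2: int) -> float:
    """Two-sided Fisher's exact p: sum of hypergeometric probabilities no
    larger than that of the observed table."""
    table = [[x1, n1 - x1], [x2, n2 - x2]]
    return float(stats.fisher_exact(table, alternative="two-sided")[1])


def wilcoxon_rank_sum(a, b) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    Exact enumeration of the rank-sum distribution when ``len(a)+len(b)<=12``
    and there are no ties; otherwise the normal approximation with tie and
    continuity corrections.  Returns ``(W, p)`` with ``W`` the Mann-Whitney
    U statistic of the first sample.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < pooled.size
    if np.ptp(pooled) == 0:
        # identical constant samples: no evidence either way
        u = a.size * b.size / 2
        return float(u), 1.0
    if a.size + b.size <= 12 and not has_ties:
        ranks = stats.rankdata(pooled)
        w_obs = ranks[: a.size].sum()
        n = pooled.size
        all_ranks = np.arange(1, n + 1)
        sums = np.array([sum(c) for c in combinations(all_ranks, a.size)])
        mean_w = sums.mean()
        p = np.mean(np.abs(sums - mean_w) >= np.abs(w_obs - mean_w) - 1e-12)
        u = w_obs - a.size * (a.size + 1) / 2
        return float(u), float(min(p, 1.0))
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    return float(res.statistic), float(res.pvalue)


def auc_rank(scores, labels) -> float:
    """Area under the ROC curve via the Mann-Whitney formulation.

    ``U / (n_pos * n_neg)`` with midranks for ties; ``labels`` are 0/1 with
    1 the positive class (higher scores expected for positives).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC requires both classes present")
    ranks = stats.rankdata(scores)
    u = ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2
    return float(u / (n_pos * n_neg))
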