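"""Statistical comparison of paired F1-score distributions (body vs world).

The two cross-validation F1 samples (100 values per reference frame) are
compared with a decision path mirroring common practice: Shapiro–Wilk per
group and Levene (Brown–Forsythe, median-centered) across groups; if both
groups pass normality, a two-sample t-test (pooled or Welch depending on
the variance check), otherwise the Mann–Whitney U test. The effect size is
the rank-biserial correlation 1 - 2U/(n1*n2).

The Mann–Whitney statistic and its p-value are computed in-repo (midrank
tie handling; exact null enumeration for small samples without ties,
tie-corrected normal approximation otherwise); the assumption checks are
delegated to scipy.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

logger = logging.getLogger(__name__)


@dataclass
class FrameComparison:
    group_stats: dict          # name -> {mean, median, std}
    normality_p: dict          # name -> Shapiro-Wilk p
    levene_p: float
    test_name: str             # 'mann-whitney' | 't-test' | 'welch-t'
    statistic: float
    p_value: float
    rank_biserial: float | None
    mean_diff: float
    ci95: tuple                # CI of the location difference (g1 - g2)
    decision_log: list = field(default_factory=list)


def describe(samples) -> tuple:
    """(mean, median, sample std) with the n-1 reporting convention."""
    x = np.asarray(samples, dtype=float)
    if x.size == 0:
        raise ValueError("empty sample")
    std = float(np.std(x, ddof=1)) if x.size > 1 else 0.0
    return float(np.mean(x)), float(np.median(x)), std


def _midranks(values: np.ndarray) -> np.ndarray:
    order = np.argsort(values, kind="mergesort")
    ranks = np.empty(len(values), dtype=float)
    sv = values[order]
    i = 0
    while i < len(sv):
        j = i
        while j + 1 < len(sv) and sv[j + 1] == sv[i]:
            j += 1
        ranks[order[i:j + 1]] = (i + j) / 2 + 1  # average of ranks i+1..j+1
        i = j + 1
    return ranks


def _exact_u_sf(u_ge: int, n1: int, n2: int) -> float:
    """P(U >= u_ge) under the no-tie null, by enumeration of the U counts.

    Polynomial DP over the Gaussian-binomial generating function.
    """
    max_u = n1 * n2
    # f[m][n][u]: interleavings of m group-1 and n group-2 values with U = u;
    # recursion on the largest observation: an X adds n to U, a Y adds 0.
    f = np.zeros((n1 + 1, n2 + 1, max_u + 1))
    f[0, :, 0] = 1.0
    f[:, 0, 0] = 1.0
    for m in range(1, n1 + 1):
        for n in range(1, n2 + 1):
            f[m, n, n:] += f[m - 1, n, :max_u + 1 - n]
            f[m, n, :] += f[m, n - 1, :]
    counts = f[n1, n2]
    return float(counts[u_ge:].sum() / counts.sum())


def mann_whitney_u(g1, g2) -> tuple:
    """(U of group 1, two-sided p-value).

    U = sum over all pairs of [x > y] + 0.5 [x == y], computed via
    midranks. Exact enumeration when min(n1, n2) <= 8 and no ties are
    present; otherwise normal approximation with tie correction and
    continuity correction.
    """
    g1 = np.asarray(g1, dtype=float)
    g2 = np.asarray(g2, dtype=float)
    if g1.size == 0 or g2.size == 0:
        raise ValueError("both groups must be nonempty")
    n1, n2 = g1.size, g2.size
    pooled = np.concatenate([g1, g2])
    ranks = _midranks(pooled)
    r1 = ranks[:n1].sum()
    u1 = r1 - n1 * (n1 + 1) / 2

    _, tie_counts = np.unique(pooled, return_counts=True)
    has_ties = np.any(tie_counts > 1)

    if min(n1, n2) <= 8 and not has_ties:
        u_int = int(round(u1))
        u_big = max(u_int, n1 * n2 - u_int)
        p = 2 * _exact_u_sf(u_big, n1, n2)
        return float(u1), float(min(1.0, p))

    n = n1 + n2
    mu = n1 * n2 / 2
    tie_term = float(np.sum(tie_counts ** 3 - tie_counts)) / (n * (n - 1))
    sigma2 = n1 * n2 / 12 * (n + 1 - tie_term)
    if sigma2 <= 0:
        return float(u1), 1.0  # all values identical
    z = (u1 - mu - 0.5 * np.sign(u1 - mu)) / math.sqrt(sigma2)
    p = 2 * sps.norm.sf(abs(z))
    return float(u1), float(min(1.0, p))


def rank_biserial(U: float, n1: int, n2: int) -> float:
    """Rank-biserial correlation 1 - 2U/(n1*n2), in [-1, 1]."""
    if n1 < 1 or n2 < 1:
        raise ValueError("group sizes must be >= 1")
    if not 0 <= U <= n1 * n2:
        raise ValueError(f"U={U} outside [0, {n1 * n2}]")
    return 1.0 - 2.0 * U / (n1 * n2)


def hodges_lehmann_ci(g1, g2, alpha: float = 0.05) -> tuple:
    """Hodges–Lehmann estimate and CI of the location shift (g1 - g2).

    Order statistics of the pairwise differences, with the rank offset
    from the normal approximation of the Mann–Whitney null.
    """
    g1 = np.asarray(g1, dtype=float)
    g2 = np.asarray(g2, dtype=float)
    diffs = np.sort((g1[:, None] - g2[None, :]).ravel())
    n1, n2 = g1.size, g2.size
    m = n1 * n2
    z = sps.norm.ppf(1 - alpha / 2)
    k = int(math.floor(m / 2 - z * math.sqrt(n1 * n2 * (n1 + n2 + 1) / 12)))
    k = max(k, 0)
    lo = diffs[k] if k < m else diffs[0]
    hi = diffs[m - 1 - k] if k < m else diffs[-1]
    return float(lo), float(hi)


def compare_frames(f1_group1, f1_group2, alpha: float = 0.05,
                   names=("body", "world")) -> FrameComparison:
    """Full decision-path comparison of two F1 distributions.

    Shapiro–Wilk per group, Levene (median-centered) across groups, then a
    t-test (pooled or Welch) when both groups look normal, otherwise
    Mann–Whitney with rank-biserial effect size. Zero-variance groups fall
    through to the nonparametric branch.
    """
    g1 = np.asarray(f1_group1, dtype=float)
    g2 = np.asarray(f1_group2, dtype=float)
    if g1.size < 3 or g2.size < 3:
        raise ValueError("need at least 3 values per group")
    log = []
    gstats = {names[0]: dict(zip(("mean", "median", "std"), describe(g1))),
              names[1]: dict(zip(("mean", "median", "std"), describe(g2)))}
    degenerate = np.ptp(g1) == 0 or np.ptp(g2) == 0
    if degenerate:
        logger.warning("zero-variance group; using Mann-Whitney")
        log.append("zero-variance group -> nonparametric branch")
        norm_p = {names[0]: float("nan"), names[1]: float("nan")}
        lev_p = float("nan")
        normal = False
        equal_var = False
    else:
        norm_p = {names[0]: float(sps.shapiro(g1).pvalue),
                  names[1]: float(sps.shapiro(g2).pvalue)}
        lev_p = float(sps.levene(g1, g2, center="median").pvalue)
        normal = all(p > alpha for p in norm_p.values())
        equal_var = lev_p > alpha
        log.append(f"shapiro p: {norm_p}; levene p: {lev_p:.4g}")

    mean_diff = float(np.mean(g1) - np.mean(g2))
    if normal:
        res = sps.ttest_ind(g1, g2, equal_var=equal_var)
        test_name = "t-test" if equal_var else "welch-t"
        log.append(f"both groups normal -> {test_name}")
        se = math.sqrt(np.var(g1, ddof=1) / g1.size + np.var(g2, ddof=1) / g2.size)
        z = sps.norm.ppf(1 - alpha / 2)
        ci = (mean_diff - z * se, mean_diff + z * se)
        rb = None
        stat, p = float(res.statistic), float(res.pvalue)
    else:
        log.append("normality rejected -> mann-whitney")
        stat, p = mann_whitney_u(g1, g2)
        rb = rank_biserial(stat, g1.size, g2.size)
        ci = hodges_lehmann_ci(g1, g2, alpha=alpha)
        test_name = "mann-whitney"
    return FrameComparison(
        group_stats=gstats, normality_p=norm_p, levene_p=lev_p,
        test_name=test_name, statistic=stat, p_value=p,
        rank_biserial=rb, mean_diff=mean_diff, ci95=ci, decision_log=log,
    )


def comparison_to_dict(cmp: FrameComparison) -> dict:
    return {
        "group_stats": cmp.group_stats,
        "normality_p": cmp.normality_p,
        "levene_p": cmp.levene_p,
        "test": cmp.test_name,
        "statistic": cmp.statistic,
        "p_value": cmp.p_value,
        "rank_biserial": cmp.rank_biserial,
        "mean_diff": cmp.mean_diff,
        "ci95": list(cmp.ci95),
        "decision_log": cmp.decision_log,
    }
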