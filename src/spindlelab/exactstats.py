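"""Exact small-sample nonparametric tests.

All group comparisons in this package use rank-based tests whose null
distributions are computed by exact enumeration whenever the data permit
(no cross-group ties for the Mann-Whitney U, no tied absolute differences
for the Wilcoxon signed-rank).  Exactness matters here because the sample
sizes are tiny (3-14 subjects): the printed minima attainable under
complete separation (1/C(n1+n2, n1) for Mann-Whitney, 1/2**n for
Wilcoxon) are themselves checkable analytic quantities.

The enumeration is carried out with a dynamic-programming convolution
over rank sums, which is arithmetically identical to walking all
C(n1+n2, n1) subsets (resp. 2**n sign patterns) but runs in polynomial
time.  With ties the exact null is no longer distribution-free and the
functions fall back to the midrank normal approximation with a warning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from math import comb, sqrt

import numpy as np
from scipy import stats

__all__ = [
    "ExactTestResult",
    "KruskalDunnResult",
    "mannwhitney_exact",
    "wilcoxon_exact",
    "kruskal_dunn",
]

#: above this many enumerable outcomes the exact path is abandoned
MAX_EXACT_OUTCOMES = 10**7


@dataclass
class ExactTestResult:
    """Outcome of an exact (or approximate) rank test."""

    statistic: float
    p: float
    sided: str                      # "one" or "two"
    n_config: tuple[int, ...]       # sample sizes entering the test
    method: str                     # "exact_enumeration" | "normal_approx"
    warnings: list[str] = field(default_factory=list)


def _normalize_sided(sided: str) -> str:
    s = str(sided).lower()
    if s in ("one", "one-sided", "1"):
        return "one"
    if s in ("two", "two-sided", "2"):
        return "two"
    if s in ("greater", "less"):
        return s
    raise ValueError(
        f"sided must be 'one', 'two', 'greater' or 'less', got {sided!r}")


def _tail_p(p_ge: float, p_le: float, sided: str) -> float:
    """Map the two tail probabilities onto the requested sidedness.

    ``"one"`` is the tail in the direction of the observed effect (the
    smaller tail), matching how directional hypotheses are reported for
    these tests; ``"greater"``/``"less"`` pin the direction explicitly.
    """
    if sided == "greater":
        return p_ge
    if sided == "less":
        return p_le
    if sided == "one":
        return min(p_ge, p_le)
    return min(1.0, 2.0 * min(p_ge, p_le))


def _mw_null_counts(n1: int, n2: int) -> np.ndarray:
    """Null distribution of the Mann-Whitney U for group sizes n1, n2.

    counts[u] = number of the C(n1+n2, n1) equally likely rank subsets in
    which the first group attains U = u.  Subset-sum dynamic programme
    over the ranks 1..n1+n2; identical to brute-force enumeration.
    """
    n_total = n1 + n2
    max_sum = n_total * (n_total + 1) // 2
    # dp[k, s] = number of size-k subsets of the ranks seen so far with sum s
    dp = np.zeros((n1 + 1, max_sum + 1), dtype=float)
    dp[0, 0] = 1.0
    for r in range(1, n_total + 1):
        for k in range(min(r, n1), 0, -1):
            dp[k, r:] += dp[k - 1, : max_sum + 1 - r]
    min_sum = n1 * (n1 + 1) // 2
    return dp[n1, min_sum : min_sum + n1 * n2 + 1].copy()


def mannwhitney_exact(x, y, sided: str = "one") -> ExactTestResult:
    """Mann-Whitney U test of x against y.

    ``sided="one"`` reports the tail probability in the direction of the
    observed effect; ``"greater"``/``"less"`` fix the direction (x vs y).
    Exact p by enumeration of all C(n1+n2, n1) rank arrangements when
    there are no cross-group ties; midrank normal approximation otherwise.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    sided = _normalize_sided(sided)
    n1, n2 = x.size, y.size

    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    warns: list[str] = []

    ranks = stats.rankdata(pooled)
    u_x = ranks[:n1].sum() - n1 * (n1 + 1) / 2.0

    n_outcomes = comb(n1 + n2, n1)
    if has_ties or n_outcomes > MAX_EXACT_OUTCOMES:
        if has_ties:
            warns.append("ties present: midrank normal approximation used")
            warnings.warn(warns[-1], stacklevel=2)
        p_ge = stats.mannwhitneyu(x, y, alternative="greater",
                                  method="asymptotic").pvalue
        p_le = stats.mannwhitneyu(x, y, alternative="less",
                                  method="asymptotic").pvalue
        return ExactTestResult(float(u_x), _tail_p(p_ge, p_le, sided), sided,
                               (n1, n2), "normal_approx", warns)

    counts = _mw_null_counts(n1, n2)
    total = counts.sum()          # == C(n1+n2, n1)
    u_int = int(round(u_x))
    p_ge = counts[u_int:].sum() / total
    p_le = counts[: u_int + 1].sum() / total
    p = _tail_p(p_ge, p_le, sided)
    return ExactTestResult(float(u_x), float(p), sided, (n1, n2),
                           "exact_enumeration", warns)


def _wilcoxon_null_counts(ranks: np.ndarray) -> np.ndarray:
    """counts[w2] = sign patterns with 2*W+ = w2 for the given ranks.

    Works on doubled ranks so midranks (x.5 under tied |differences|)
    stay integral; with untied data this is the classic signed-rank
    null over ranks 1..n.
    """
    r2 = np.round(2 * np.asarray(ranks, dtype=float)).astype(int)
    max_w = int(r2.sum())
    counts = np.zeros(max_w + 1, dtype=float)
    counts[0] = 1.0
    for r in r2:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[:max_w + 1 - r]
        counts = counts + shifted
    return counts


def wilcoxon_exact(diffs, sided: str = "one") -> ExactTestResult:
    """Wilcoxon signed-rank test on paired differences.

    Zero differences are dropped before ranking (classic Wilcoxon
    convention), so the one-sided p under complete separation of n
    nonzero pairs is exactly 1/2**n.  Tied |differences| take midranks;
    the sign-flip null is enumerated conditionally on the observed
    |differences|, so the test stays exact under ties.  ``sided="one"``
    reports the tail in the direction of the observed effect;
    ``"greater"`` tests for positive differences, ``"less"`` for
    negative.
    """
    d = np.asarray(diffs, dtype=float).ravel()
    if d.size == 0:
        raise ValueError("no differences supplied")
    sided = _normalize_sided(sided)
    d = d[d != 0.0]
    if d.size == 0:
        raise ValueError("all differences are zero; test undefined")
    n = d.size

    ranks = stats.rankdata(np.abs(d))
    w_plus = ranks[d > 0].sum()
    warns: list[str] = []

    if 2**n > MAX_EXACT_OUTCOMES:
        p_ge = stats.wilcoxon(d, alternative="greater", method="approx",
                              correction=False).pvalue
        p_le = stats.wilcoxon(d, alternative="less", method="approx",
                              correction=False).pvalue
        return ExactTestResult(float(w_plus), _tail_p(p_ge, p_le, sided),
                               sided, (n,), "normal_approx", warns)

    counts = _wilcoxon_null_counts(ranks)
    total = counts.sum()           # == 2**n
    w2 = int(round(2 * w_plus))
    p_ge = counts[w2:].sum() / total
    p_le = counts[: w2 + 1].sum() / total
    p = _tail_p(p_ge, p_le, sided)
    return ExactTestResult(float(w_plus), float(p), sided, (n,),
                           "exact_enumeration", warns)


@dataclass
class KruskalDunnResult:
    h_statistic: float
    p_omnibus: float
    pairwise: list[dict]           # group_i, group_j, z, p (unadjusted), p_adj
    n_config: tuple[int, ...]


def kruskal_dunn(groups, adjust: str | None = None) -> KruskalDunnResult:
    """Kruskal-Wallis omnibus test followed by Dunn's pairwise z tests.

    Dunn p-values are reported unadjusted by default; ``adjust="holm"``
    applies a step-down correction via statsmodels.
    """
    groups = [np.asarray(g, dtype=float).ravel() for g in groups]
    if len(groups) < 3:
        raise ValueError("kruskal_dunn requires at least 3 groups")
    if any(g.size == 0 for g in groups):
        raise ValueError("empty group supplied")

    h, p_omni = stats.kruskal(*groups)

    pooled = np.concatenate(groups)
    n_total = pooled.size
    ranks = stats.rankdata(pooled)
    # tie correction term sum(t^3 - t) over tied groups
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts))

    mean_ranks, sizes = [], []
    start = 0
    for g in groups:
        mean_ranks.append(ranks[start : start + g.size].mean())
        sizes.append(g.size)
        start += g.size

    pairwise = []
    raw_ps = []
    var_base = n_total * (n_total + 1) / 12.0 - tie_term / (12.0 * (n_total - 1))
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            se = sqrt(var_base * (1.0 / sizes[i] + 1.0 / sizes[j]))
            z = (mean_ranks[i] - mean_ranks[j]) / se
            p = 2.0 * stats.norm.sf(abs(z))
            pairwise.append({"group_i": i, "group_j": j,
                             "z": float(z), "p": float(p)})
            raw_ps.append(p)

    if adjust is not None:
        from statsmodels.stats.multitest import multipletests

        _, p_adj, _, _ = multipletests(raw_ps, method=adjust)
        for rec, pa in zip(pairwise, p_adj):
            rec["p_adj"] = float(pa)

    return KruskalDunnResult(float(h), float(p_omni), pairwise, tuple(sizes))
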