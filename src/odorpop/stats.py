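"""Inferential procedures used by the pipeline.

Welch's heteroscedastic one-way ANOVA, the Brown-Forsythe ANOVA (for means),
and the Games-Howell post-hoc are implemented here; Mann-Whitney U and the
exact binomial test delegate to scipy with the pipeline's conventions
(exact/asymptotic switch, one-sided tails).

Welch's F with k groups of size n_i, mean m_i, variance s_i²:

    w_i = n_i / s_i²,  W = Σ w_i,  m_w = Σ w_i m_i / W
    F = [Σ w_i (m_i − m_w)² / (k−1)] / [1 + 2(k−2)/(k²−1) · Λ]
    Λ = Σ (1 − w_i/W)² / (n_i − 1),  df = (k−1, (k²−1)/(3Λ))

Brown-Forsythe F* for equality of means:

    F* = Σ n_i (m_i − m)² / Σ (1 − n_i/N) s_i²

with Satterthwaite denominator df.  Games-Howell compares each pair with a
Welch-type t, refers q = t·√2 to the studentized range with k groups, and is
therefore valid under unequal variances and sizes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as _stats


@dataclass
class TestResult:
    statistic: float
    df: tuple[float, ...] | float | None
    p: float
    test: str
    tails: str = "two-sided"


def _group_stats(groups):
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    n = np.array([g.size for g in groups], dtype=float)
    if np.any(n < 2):
        raise ValueError("each group needs n >= 2")
    m = np.array([g.mean() for g in groups])
    v = np.array([g.var(ddof=1) for g in groups])
    return groups, n, m, v


def welch_anova(groups) -> TestResult:
    """Welch's heteroscedastic one-way ANOVA across k groups."""
    _, n, m, v = _group_stats(groups)
    if np.any(v == 0):
        raise ValueError("zero-variance group: Welch ANOVA undefined")
    k = len(n)
    w = n / v
    W = w.sum()
    mw = (w * m).sum() / W
    lam = (((1.0 - w / W) ** 2) / (n - 1.0)).sum()
    num = (w * (m - mw) ** 2).sum() / (k - 1)
    den = 1.0 + 2.0 * (k - 2) / (k**2 - 1.0) * lam
    F = num / den
    df2 = (k**2 - 1.0) / (3.0 * lam)
    p = float(_stats.f.sf(F, k - 1, df2))
    return TestResult(float(F), (k - 1.0, float(df2)), p, "welch_anova")


def brown_forsythe_anova(groups) -> TestResult:
    """Brown-Forsythe ANOVA for equality of group means."""
    _, n, m, v = _group_stats(groups)
    if np.any(v == 0):
        raise ValueError("zero-variance group: Brown-Forsythe ANOVA undefined")
    k = len(n)
    N = n.sum()
    grand = (n * m).sum() / N
    num = (n * (m - grand) ** 2).sum()
    terms = (1.0 - n / N) * v
    den = terms.sum()
    if num == 0.0:
        return TestResult(0.0, (k - 1.0, float("nan")), 1.0, "brown_forsythe_anova")
    F = num / den
    c = terms / den
    df2 = 1.0 / ((c**2 / (n - 1.0)).sum())
    p = float(_stats.f.sf(F, k - 1, df2))
    return TestResult(float(F), (k - 1.0, float(df2)), p, "brown_forsythe_anova")


def games_howell(groups, labels=None):
    """Games-Howell pairwise post-hoc p-value matrix.

    Per pair (i, j): t = |m_i − m_j| / sqrt(s_i²/n_i + s_j²/n_j) with the
    Welch-Satterthwaite df; p from the studentized-range distribution with
    the full number of groups at q = t·√2.  Returns a symmetric
    ``(k, k)`` array with 1.0 on the diagonal (and ``labels`` order).
    Degenerate pairs (both variances zero) are flagged NaN unless the means
    agree, in which case p = 1.
    """
    groups, n, m, v = _group_stats(groups)
    k = len(groups)
    P = np.ones((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            se2 = v[i] / n[i] + v[j] / n[j]
            if se2 == 0.0:
                p = 1.0 if m[i] == m[j] else np.nan
            else:
                t = abs(m[i] - m[j]) / np.sqrt(se2)
                df = se2**2 / (
                    (v[i] / n[i]) ** 2 / (n[i] - 1) + (v[j] / n[j]) ** 2 / (n[j] - 1)
                )
                q = t * np.sqrt(2.0)
                p = float(_stats.studentized_range.sf(q, k, df))
            P[i, j] = P[j, i] = p
    return (P, list(labels)) if labels is not None else P


def mann_whitney_u(a, b, tails: str = "two-sided") -> TestResult:
    """Mann-Whitney U test.

    Exact enumeration when n_a·n_b <= 200 and the data are tie-free;
    tie-corrected normal approximation otherwise.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("empty group")
    has_ties = np.unique(np.concatenate([a, b])).size < a.size + b.size
    method = "exact" if (a.size * b.size <= 200 and not has_ties) else "asymptotic"
    res = _stats.mannwhitneyu(a, b, alternative=tails, method=method)
    return TestResult(float(res.statistic), None, float(res.pvalue),
                      f"mann_whitney_u[{method}]", tails)


def binomial_test_one_sided(successes: int, n: int, p0: float,
                            direction: str = "greater") -> TestResult:
    """Exact one-sided binomial tail probability P(X >= k) (or <=)."""
    if not 0 <= successes <= n:
        raise ValueError("need 0 <= successes <= n")
    if not 0.0 < p0 < 1.0:
        raise ValueError("p0 must lie in (0, 1)")
    if direction not in ("greater", "less"):
        raise ValueError("direction must be greater or less")
    res = _stats.binomtest(successes, n, p0, alternative=direction)
    return TestResult(float(successes), None, float(res.pvalue),
                      "binomial", direction)


def two_proportion_test(k1: int, n1: int, k2: int, n2: int) -> TestResult:
    """Two-sided pooled two-proportion z-test."""
    if min(n1, n2) < 1:
        raise ValueError("empty sample")
    p1, p2 = k1 / n1, k2 / n2
    pool = (k1 + k2) / (n1 + n2)
    se = np.sqrt(pool * (1 - pool) * (1 / n1 + 1 / n2))
    if se == 0.0:
        return TestResult(0.0, None, 1.0, "two_proportion_z")
    z = (p1 - p2) / se
    p = float(2 * _stats.norm.sf(abs(z)))
    return TestResult(float(z), None, p, "two_proportion_z")
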