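"""Two-sided statistical tests used throughout the pipeline.

Thin, convention-pinning wrappers around scipy.stats plus an exact test for
2x3 contingency tables (which scipy does not provide).  Conventions:

* Mann-Whitney U: exact enumeration when the combined sample size is <= 20
  and there are no ties; tie-corrected normal approximation otherwise.
* Fisher's exact test (2x2 and 2x3): two-sided by the minimum-likelihood
  rule — the p-value sums the probabilities of all tables, under the fixed
  margins, that are no more probable than the observed one.
* Degenerate inputs (zero variance where a t statistic needs one) are
  flagged rather than silently returning NaN.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from scipy.special import gammaln


@dataclass(frozen=True)
class StatResult:
    statistic: float
    pvalue: float
    method: str
    note: str = ""


def asdict(r: StatResult) -> dict:
    return dataclasses.asdict(r)


def mann_whitney_u(x, y) -> StatResult:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("Mann-Whitney requires at least 2 observations per group")
    combined = np.concatenate([x, y])
    has_ties = np.unique(combined).size < combined.size
    method = "exact" if (combined.size <= 20 and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return StatResult(float(res.statistic), float(res.pvalue),
                      f"Mann-Whitney U ({method})")


def fisher_exact_2x2(table) -> StatResult:
    table = np.asarray(table, dtype=int)
    if table.shape != (2, 2) or (table < 0).any():
        raise ValueError("need a 2x2 table of nonnegative counts")
    odds, p = sps.fisher_exact(table, alternative="two-sided")
    return StatResult(float(odds), float(p), "Fisher exact (2x2)")


def fisher_exact_2x3(table) -> StatResult:
    """Freeman-Halton exact test for a 2x3 table.

    Enumerates the full support of tables with the observed margins and sums
    the hypergeometric probabilities of tables no more likely than the
    observed one.  Quadratic in the table total; intended for the few hundred
    neurons of a classification table.
    """
    table = np.asarray(table, dtype=int)
    if table.shape != (2, 3) or (table < 0).any():
        raise ValueError("need a 2x3 table of nonnegative counts")
    r1, r2 = table.sum(axis=1)
    c = table.sum(axis=0)
    n = table.sum()

    def logp(a, b):
        cells = np.array([a, b, r1 - a - b, c[0] - a, c[1] - b, r2 - (c[0] - a) - (c[1] - b)])
        return (gammaln(r1 + 1) + gammaln(r2 + 1) + gammaln(c + 1).sum()
                - gammaln(n + 1) - gammaln(cells + 1).sum())

    obs = logp(table[0, 0], table[0, 1])
    total = 0.0
    p_obs = 0.0
    for a in range(max(0, r1 - c[1] - c[2]), min(r1, c[0]) + 1):
        b_lo = max(0, r1 - a - c[2])
        b_hi = min(r1 - a, c[1])
        for b in range(b_lo, b_hi + 1):
            lp = logp(a, b)
            pr = float(np.exp(lp))
            total += pr
            if lp <= obs + 1e-10:
                p_obs += pr
    return StatResult(float(np.exp(obs)), min(1.0, p_obs / total),
                      "Freeman-Halton exact (2x3)")


def student_t(x, y) -> StatResult:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("Student's t requires at least 2 observations per group")
    if np.var(x, ddof=1) == 0 and np.var(y, ddof=1) == 0:
        if x.mean() == y.mean():
            return StatResult(0.0, 1.0, "Student t", "both samples constant and equal")
        return StatResult(np.nan, np.nan, "Student t", "degenerate: zero variance")
    res = sps.ttest_ind(x, y, equal_var=True)
    return StatResult(float(res.statistic), float(res.pvalue), "Student t")


def paired_t(x, y) -> StatResult:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired samples must have equal length")
    if x.size < 2:
        raise ValueError("paired t requires at least 2 pairs")
    d = x - y
    if np.all(d == 0):
        return StatResult(0.0, 1.0, "paired t", "all differences zero")
    if np.var(d, ddof=1) == 0:
        return StatResult(np.nan, np.nan, "paired t",
                          "degenerate: zero variance of differences")
    res = sps.ttest_rel(x, y)
    return StatResult(float(res.statistic), float(res.pvalue), "paired t")


def one_sample_t(x, mu: float) -> StatResult:
    x = np.asarray(x, dtype=float)
    if x.size < 1:
        raise ValueError("one-sample t requires at least 1 observation")
    if np.var(x, ddof=1) == 0 or x.size < 2:
        return StatResult(np.nan, np.nan, "one-sample t",
                          "degenerate: zero variance")
    res = sps.ttest_1samp(x, mu)
    return StatResult(float(res.statistic), float(res.pvalue), "one-sample t")
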