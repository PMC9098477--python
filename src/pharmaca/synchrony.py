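"""Pairwise synchrony via a lag-limited, activity-normalised cross-correlogram.

For two deconvolved trains x1, x2 over T frames with total activities s1, s2,
the synchrony statistic is

    CCG = max over tau in {-1, 0, +1} of  sum_t x1(t) * x2(t + tau) / sqrt(s1 * s2)

Out-of-range indices at the segment edges contribute zero (no wraparound).
Note the normalisation is by total activities, not L2 norms, so the statistic
is not bounded by 1 and scales as sqrt(c) when one train is multiplied by c.

Significance uses a shuffle null: both trains' frame orders are permuted
independently and the CCG recomputed (default 10,000 iterations); a pair is
synchronous if the real CCG strictly exceeds the top-1% null cutoff.  The
null is sampled sparsely and exactly: a permutation places each train's
nonzero frame values on a uniformly random ordered tuple of distinct frame
positions, so only event positions are drawn and lag coincidences are found
by integer-code matching — O(iterations * events) instead of
O(iterations * frames).

Eligibility mirrors the response stage: only excited and stable neurons with
post-epoch activity >= 3000 a.u. enter the pair analysis (the statistic is
activity-normalised, yet low-activity neurons still bias the synchronous-pair
proportion), and pairs are formed within a response group only.
"""
from __future__ import annotations

from itertools import combinations

import numpy as np
import pandas as pd

from . import stats
from .dataio import AnalysisConfig, SessionData

DEFAULT_LAGS = (-1, 0, 1)


class ZeroActivityError(ValueError):
    """A train has zero total activity; the normalised CCG is undefined."""


def _lag_sum(x1: np.ndarray, x2: np.ndarray, tau: int) -> float:
    # sum_t x1(t) * x2(t + tau), truncated at segment edges
    if tau >= 0:
        return float(np.dot(x1[:x1.size - tau or None], x2[tau:]))
    return float(np.dot(x1[-tau:], x2[:tau]))


def ccg(x1, x2, lags=DEFAULT_LAGS) -> float:
    """Cross-correlogram statistic of two equal-length train segments."""
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    if x1.shape != x2.shape:
        raise ValueError("trains must have equal length")
    s1, s2 = x1.sum(), x2.sum()
    if s1 <= 0 or s2 <= 0:
        raise ZeroActivityError("CCG undefined for a train with zero total activity")
    return max(_lag_sum(x1, x2, tau) for tau in lags) / np.sqrt(s1 * s2)


def _sample_distinct_positions(rng, n_iters: int, n_frames: int, k: int) -> np.ndarray:
    """(n_iters, k) uniform ordered tuples of distinct frame positions.

    Per iteration this is exactly where a uniform frame permutation sends the
    k nonzero frames of a train; sampling without replacement in O(k) per
    iteration replaces materialising length-T permutations.
    """
    if k == 0:
        return np.empty((n_iters, 0), dtype=np.int64)
    out = np.empty((n_iters, k), dtype=np.int64)
    for i in range(n_iters):
        out[i] = rng.choice(n_frames, size=k, replace=False)
    return out


def ccg_null(x1, x2, n_iters: int, rng, lags=DEFAULT_LAGS) -> np.ndarray:
    """Null CCG distribution under independent frame permutations of both trains."""
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    if x1.shape != x2.shape:
        raise ValueError("trains must have equal length")
    T = x1.size
    s1, s2 = x1.sum(), x2.sum()
    if s1 <= 0 or s2 <= 0:
        raise ZeroActivityError("CCG null undefined for a zero-activity train")
    a = x1[x1 > 0]
    b = x2[x2 > 0]
    k1, k2 = a.size, b.size
    P = _sample_distinct_positions(rng, n_iters, T, k1)
    Q = _sample_distinct_positions(rng, n_iters, T, k2)

    # integer codes: one block of width T+3 per iteration; +1 keeps shifted
    # positions (-1 .. T) inside the block, so edge lags simply never match.
    stride = T + 3
    rows1 = np.repeat(np.arange(n_iters, dtype=np.int64), k1)
    rows2 = np.repeat(np.arange(n_iters, dtype=np.int64), k2)
    c2 = rows2 * stride + Q.ravel() + 1
    order = np.argsort(c2)
    c2s = c2[order]
    b_sorted = np.broadcast_to(b, Q.shape).ravel()[order]
    a_flat = np.broadcast_to(a, P.shape).ravel()

    best = np.zeros(n_iters)
    base_c1 = rows1 * stride + P.ravel() + 1
    for tau in lags:
        c1 = base_c1 + tau
        idx = np.searchsorted(c2s, c1)
        idx_c = np.minimum(idx, c2s.size - 1)
        hit = (idx < c2s.size) & (c2s[idx_c] == c1)
        if hit.any():
            contrib = np.zeros(n_iters)
            np.add.at(contrib, rows1[hit], a_flat[hit] * b_sorted[idx_c[hit]])
            np.maximum(best, contrib, out=best)
    return best / np.sqrt(s1 * s2)


def null_threshold(null: np.ndarray, tail: float) -> float:
    """Top-``tail`` cutoff: the k-th largest null value, k = round(tail * n)."""
    n = null.size
    k = max(1, int(round(tail * n)))
    return float(np.partition(null, n - k)[n - k])


def synchrony_filter(results: pd.DataFrame, config: AnalysisConfig) -> pd.DataFrame:
    """Neurons eligible for the pair analysis.

    Keeps excited and stable neurons with a_after >= ccg_activity_min
    (the complement of the strict "< 3000" exclusion).  Inhibited neurons are
    not analysed.
    """
    keep = results["label"].isin(("excited", "stable")) & (
        results["a_after"] >= config.ccg_activity_min)
    return results.loc[keep, ["neuron_id", "label", "a_after"]].reset_index(drop=True)


def detect_synchronous_pairs(session: SessionData, results: pd.DataFrame,
                             config: AnalysisConfig, rng):
    """CCG every within-group pair of eligible neurons against its shuffle null.

    The statistic is computed on the post-injection epoch by default (the
    eligibility floor is on post-epoch activity).  Returns
    ``(pairs, summaries, comparison)``: a per-pair DataFrame, per-group pair
    counts/proportions, and a two-sided Fisher 2x2 comparison of synchronous-
    pair proportions between the excited and stable groups (None when either
    group has no pairs).
    """
    seg = session.post if config.ccg_epoch == "post" else session.pre
    eligible = synchrony_filter(results, config)
    rows = []
    summaries = {}
    for group in ("excited", "stable"):
        ids = eligible.loc[eligible["label"] == group, "neuron_id"].astype(int).tolist()
        pairs = list(combinations(ids, 2))
        n_sync = 0
        if pairs:
            child_rngs = rng.spawn(len(pairs))
            for (i, j), child in zip(pairs, child_rngs):
                stat = ccg(seg[i], seg[j])
                null = ccg_null(seg[i], seg[j], config.ccg_null_iters, child)
                thr = null_threshold(null, config.ccg_tail)
                flag = bool(stat > thr)
                n_sync += flag
                rows.append(dict(neuron_i=i, neuron_j=j, group=group,
                                 ccg=stat, threshold=thr, synchronous=flag))
        summaries[group] = dict(
            n_pairs_total=len(pairs), n_pairs_synchronous=int(n_sync),
            proportion=(n_sync / len(pairs)) if pairs else np.nan)
    comparison = None
    exc, sta = summaries["excited"], summaries["stable"]
    if exc["n_pairs_total"] > 0 and sta["n_pairs_total"] > 0:
        table = [[exc["n_pairs_synchronous"],
                  exc["n_pairs_total"] - exc["n_pairs_synchronous"]],
                 [sta["n_pairs_synchronous"],
                  sta["n_pairs_total"] - sta["n_pairs_synchronous"]]]
        comparison = stats.asdict(stats.fisher_exact_2x2(table))
    pairs_df = pd.DataFrame(
        rows, columns=["neuron_i", "neuron_j", "group", "ccg", "threshold",
                       "synchronous"])
    return pairs_df, summaries, comparison
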