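"""Per-neuron response scoring and permutation-null classification.

A neuron's response to the injection is summarised by the activity score

    score = (A_after - A_before) / (A_after + A_before)

where A_before / A_after are its total deconvolved activity over the pre /
post epoch.  The score lies in [-1, +1]; -1 means all activity preceded the
injection, +1 that all followed it.  Neurons whose baseline A_before falls
outside an inclusive window (default [1000, 4000] a.u.) are excluded: for
nearly silent or saturated baselines the score is dominated by the baseline
itself rather than by any treatment effect.

Significance is assessed against a temporal-shuffle null: the frame order of
the full-session train is permuted uniformly at random and the score
recomputed (default 100,000 iterations).  A neuron is "excited" if its real
score strictly exceeds the upper 0.1% tail of its own null, "inhibited" if
strictly below the lower 0.1% tail, otherwise "stable".  Each neuron gets its
own null because the null width depends on that neuron's amplitude multiset.

Calcium events are frames with amplitude > 0; event frequency is the count
per 10-min epoch, scored with the same normalised-contrast formula, and event
sizes are amplitudes normalised by the neuron's mean pre-epoch event
amplitude (so pre-epoch sizes average exactly 1).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import stats
from .dataio import AnalysisConfig, ConfigError, SessionData

LABELS = ("excited", "inhibited", "stable", "excluded")


class DegenerateScoreError(ValueError):
    """Raised when a score is undefined because both epoch totals are zero."""


@dataclass(frozen=True)
class EpochActivity:
    a_before: float
    a_after: float

    def __post_init__(self):
        if self.a_before < 0 or self.a_after < 0:
            raise ValueError("epoch totals must be nonnegative")


@dataclass
class EventMetrics:
    f_before: int
    f_after: int
    frequency_score: float
    sizes_pre: np.ndarray | None  # normalised; None when no pre-epoch events
    sizes_post: np.ndarray | None


def epoch_totals(train: np.ndarray, injection_frame: int) -> EpochActivity:
    """Total deconvolved activity over the pre and post epochs."""
    train = np.asarray(train, dtype=float)
    return EpochActivity(float(train[:injection_frame].sum()),
                         float(train[injection_frame:].sum()))


def activity_score(e: EpochActivity) -> float:
    total = e.a_before + e.a_after
    if total <= 0:
        raise DegenerateScoreError("activity score undefined: both epoch totals are zero")
    return (e.a_after - e.a_before) / total


def baseline_filter(e: EpochActivity, lo: float, hi: float) -> bool:
    """Keep a neuron iff lo <= A_before <= hi (bounds inclusive)."""
    if lo >= hi:
        raise ValueError("lower baseline limit must be below the upper limit")
    return lo <= e.a_before <= hi


def _shuffled_before_sums(values: np.ndarray, n_frames: int, n_before: int,
                          n_iters: int, rng) -> np.ndarray:
    """Pre-epoch totals under uniform permutations of the frame order.

    Only the k nonzero frame values matter.  A uniform permutation places
    them on a uniformly random k-subset of frame positions, so the indicator
    "value t lands in the pre epoch" follows the sequential hypergeometric
    scheme P(take_t | history) = remaining_pre_slots / remaining_frames.
    Sampling those indicators directly costs O(k * n_iters) instead of
    materialising permutations of length n_frames, and is exact.
    """
    k = values.size
    out = np.zeros(n_iters)
    if k == 0:
        return out
    u = rng.random((k, n_iters), dtype=np.float32)
    rem = np.full(n_iters, float(n_before), dtype=np.float32)
    for t in range(k):
        take = u[t] * (n_frames - t) < rem
        out += values[t] * take
        rem -= take
    return out


def score_null(train: np.ndarray, injection_frame: int, n_iters: int, rng,
               scheme: str = "permutation") -> np.ndarray:
    """Null distribution of activity scores under temporal shuffling.

    ``scheme`` selects the shuffle: "permutation" (uniform random permutation
    of all frame positions; destroys the pre/post contrast while preserving
    the amplitude multiset exactly) or "circular" (random circular shift,
    preserving within-train structure).
    """
    train = np.asarray(train, dtype=float)
    total = train.sum()
    if total <= 0:
        raise DegenerateScoreError("null undefined for an all-zero train")
    nonzero = train[train > 0]
    if nonzero.size <= 1:
        warnings.warn("degenerate train (<= 1 nonzero frame): null collapses "
                      "to {-score, +score}", stacklevel=2)
    if scheme == "permutation":
        before = _shuffled_before_sums(nonzero, train.size, injection_frame,
                                       n_iters, rng)
    elif scheme == "circular":
        cs = np.concatenate([[0.0], np.cumsum(np.concatenate([train, train]))])
        shifts = rng.integers(0, train.size, size=n_iters)
        before = cs[shifts + injection_frame] - cs[shifts]
    else:
        raise ConfigError(f"unknown shuffle scheme {scheme!r}")
    return (total - 2.0 * before) / total


def null_thresholds(null: np.ndarray, tail: float) -> tuple[float, float]:
    """Lower/upper tail cutoffs: the k-th smallest and k-th largest null score,
    k = round(tail * n_iters) (at 100,000 iterations and 0.1% tails, the
    100th from each end)."""
    n = null.size
    if n == 0:
        raise ValueError("empty null distribution")
    k = max(1, int(round(tail * n)))
    s = np.sort(null)
    return float(s[k - 1]), float(s[n - k])


def classify_response(score: float, null: np.ndarray, tail: float):
    """Label a neuron by strict comparison of its score with the null tails.

    "excited" iff score > upper cutoff, "inhibited" iff score < lower cutoff,
    else "stable".  Scores exactly equal to a cutoff are stable (the rule is
    strictly "higher than" / "lower than" the tail).
    """
    lo, hi = null_thresholds(null, tail)
    if score > hi:
        return "excited", lo, hi
    if score < lo:
        return "inhibited", lo, hi
    return "stable", lo, hi


def event_metrics(train: np.ndarray, injection_frame: int) -> EventMetrics:
    """Event counts per epoch, frequency score, and normalised event sizes."""
    train = np.asarray(train, dtype=float)
    pre, post = train[:injection_frame], train[injection_frame:]
    amps_pre = pre[pre > 0]
    amps_post = post[post > 0]
    f_before, f_after = amps_pre.size, amps_post.size
    denom = f_before + f_after
    freq_score = (f_after - f_before) / denom if denom > 0 else np.nan
    if f_before == 0:
        sizes_pre = sizes_post = None  # normalisation undefined; flagged by None
    else:
        mean_pre = amps_pre.mean()
        sizes_pre = amps_pre / mean_pre
        sizes_post = amps_post / mean_pre
    return EventMetrics(f_before, f_after, float(freq_score), sizes_pre, sizes_post)


def classify_session(session: SessionData, config: AnalysisConfig, rng):
    """Score, filter and classify every neuron of a session.

    Returns ``(results, sizes)``: a per-neuron DataFrame (id, epoch totals,
    activity score, null cutoffs, label, event counts, frequency score) and a
    long-form DataFrame of normalised event sizes (neuron_id, epoch, size)
    for neurons with a defined pre-epoch normalisation.
    """
    rows = []
    size_ids, size_epochs, size_vals = [], [], []
    child_rngs = rng.spawn(session.n_neurons)
    for i in range(session.n_neurons):
        train = session.activity[i]
        e = epoch_totals(train, session.injection_frame)
        total = e.a_before + e.a_after
        score = (e.a_after - e.a_before) / total if total > 0 else np.nan
        met = event_metrics(train, session.injection_frame)
        if baseline_filter(e, config.a_before_lo, config.a_before_hi):
            null = score_null(train, session.injection_frame,
                              config.score_null_iters, child_rngs[i],
                              scheme=config.shuffle_scheme)
            label, lo, hi = classify_response(score, null, config.score_tail)
        else:
            label, lo, hi = "excluded", np.nan, np.nan
        rows.append(dict(neuron_id=i, a_before=e.a_before, a_after=e.a_after,
                         activity_score=score, null_lo=lo, null_hi=hi,
                         label=label, f_before=met.f_before,
                         f_after=met.f_after,
                         frequency_score=met.frequency_score))
        if met.sizes_pre is not None:
            n_pre, n_post = met.sizes_pre.size, met.sizes_post.size
            size_ids.append(np.full(n_pre + n_post, i))
            size_epochs.append(np.concatenate([np.full(n_pre, "pre", dtype=object),
                                               np.full(n_post, "post", dtype=object)]))
            size_vals.append(np.concatenate([met.sizes_pre, met.sizes_post]))
    results = pd.DataFrame(rows)
    sizes = pd.DataFrame({
        "neuron_id": np.concatenate(size_ids) if size_ids else np.array([], dtype=int),
        "epoch": np.concatenate(size_epochs) if size_epochs else np.array([], dtype=object),
        "size": np.concatenate(size_vals) if size_vals else np.array([], dtype=float),
    })
    return results, sizes


def _pooled_sizes(results: pd.DataFrame, sizes: pd.DataFrame, label: str,
                  level: str) -> np.ndarray:
    ids = set(results.loc[results["label"] == label, "neuron_id"])
    sel = sizes[(sizes["epoch"] == "post") & sizes["neuron_id"].isin(ids)]
    if level == "neuron_mean":
        return sel.groupby("neuron_id")["size"].mean().to_numpy()
    return sel["size"].to_numpy()


def compare_groups(results_a: pd.DataFrame, results_b: pd.DataFrame,
                   sizes_a: pd.DataFrame | None = None,
                   sizes_b: pd.DataFrame | None = None,
                   config: AnalysisConfig | None = None) -> dict:
    """Between-treatment group statistics on classified result tables.

    Per class: two-sided Mann-Whitney U on activity and frequency scores.
    Across all classified neurons: Student's t on activity scores.  Event
    sizes (post-epoch, normalised) are compared per class, pooled at the
    event level by default.  Class counts, proportions, and an exploratory
    exact test on the 2x3 class table are included.  Comparisons with an
    empty class on either side are skipped with a note.
    """
    config = config or AnalysisConfig()
    out = {"class_counts": {}, "per_class": {}, "event_size": {}}
    for side, df in (("a", results_a), ("b", results_b)):
        counts = df["label"].value_counts().to_dict()
        out["class_counts"][side] = {lab: int(counts.get(lab, 0)) for lab in LABELS}

    kept_a = results_a[results_a["label"] != "excluded"]
    kept_b = results_b[results_b["label"] != "excluded"]
    out["n_classified"] = {"a": int(len(kept_a)), "b": int(len(kept_b))}
    if len(kept_a) >= 2 and len(kept_b) >= 2:
        t = stats.student_t(kept_a["activity_score"].to_numpy(),
                            kept_b["activity_score"].to_numpy())
        out["mean_activity_score"] = {
            "a": float(kept_a["activity_score"].mean()),
            "b": float(kept_b["activity_score"].mean()),
            "test": stats.asdict(t),
        }
    table = [[out["class_counts"]["a"][lab] for lab in ("excited", "inhibited", "stable")],
             [out["class_counts"]["b"][lab] for lab in ("excited", "inhibited", "stable")]]
    if min(sum(table[0]), sum(table[1])) > 0:
        out["proportion_test"] = stats.asdict(stats.fisher_exact_2x3(table))
        out["proportion_test"]["note"] = "exploratory"

    for lab in ("excited", "inhibited", "stable"):
        ga = results_a[results_a["label"] == lab]
        gb = results_b[results_b["label"] == lab]
        entry = {"n_a": int(len(ga)), "n_b": int(len(gb))}
        if len(ga) < 2 or len(gb) < 2:
            entry["note"] = "skipped: fewer than 2 neurons in class on one side"
            warnings.warn(f"class {lab!r} empty on one side; comparison skipped",
                          stacklevel=2)
        else:
            entry["activity_score"] = stats.asdict(stats.mann_whitney_u(
                ga["activity_score"].to_numpy(), gb["activity_score"].to_numpy()))
            fa = ga["frequency_score"].dropna().to_numpy()
            fb = gb["frequency_score"].dropna().to_numpy()
            if fa.size >= 2 and fb.size >= 2:
                entry["frequency_score"] = stats.asdict(stats.mann_whitney_u(fa, fb))
        out["per_class"][lab] = entry
        if sizes_a is not None and sizes_b is not None and lab in ("excited", "inhibited"):
            ea = _pooled_sizes(results_a, sizes_a, lab, config.event_size_level)
            eb = _pooled_sizes(results_b, sizes_b, lab, config.event_size_level)
            if ea.size >= 2 and eb.size >= 2:
                out["event_size"][lab] = stats.asdict(stats.mann_whitney_u(ea, eb))
    return out
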