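"""Decoding pre- vs post-injection epochs from binned population activity.

The 20-min session is down-sampled into 30-s bins (12,000 frames at 10 Hz ->
a neurons x 40 matrix, 20 bins labelled "before" and 20 "after").  A linear
support vector machine with an L1 penalty, trained on a stratified 70/30
split with features standardised on the training fold, classifies the bin
labels; accuracy is the test-set proportion correct.

Within a mouse, neuron counts are matched between treatments: the larger
session is decoded from random neuron subsets of the smaller session's size,
repeated (default 100 times) and averaged; the smaller session is scored
with the same number of repeated splits for symmetry.  Single-neuron
decoders and group-ablation decoders (dropping one response class from both
sessions before count matching) attribute population decodability to
response classes.

All accuracies are pure functions of (data, config, seed).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.model_selection import train_test_split
from sklearn.preprocessing import StandardScaler
from sklearn.svm import LinearSVC

from . import stats
from .dataio import AnalysisConfig, SessionData

VARIANTS = ("population", "single_neuron_mean", "minus_excited",
            "minus_inhibited", "minus_stable")


@dataclass
class BinnedActivity:
    """Summed (or averaged) activity per time bin with epoch labels."""

    X: np.ndarray  # (n_neurons, n_bins)
    labels: np.ndarray  # "before" / "after" per bin
    bin_seconds: float

    @property
    def n_bins(self) -> int:
        return self.X.shape[1]


def bin_activity(session: SessionData, bin_seconds: float | None = None,
                 config: AnalysisConfig | None = None, reducer: str | None = None,
                 truncate: bool = False) -> BinnedActivity:
    """Down-sample a session into fixed-width time bins.

    Each bin reduces its frame window with ``reducer`` ("sum" by default,
    preserving total-activity semantics of deconvolved trains).  Bin labels
    are assigned by the bin midpoint relative to the injection frame.  If the
    session length is not divisible by the bin width, raises unless
    ``truncate=True`` (which drops the trailing remainder frames).
    """
    config = config or AnalysisConfig()
    bin_seconds = bin_seconds if bin_seconds is not None else config.bin_seconds
    reducer = reducer or config.bin_reducer
    width = int(round(bin_seconds * session.frame_rate))
    if width <= 0:
        raise ValueError("bin width must span at least one frame")
    n_frames = session.n_frames
    if n_frames % width != 0 and not truncate:
        raise ValueError(
            f"n_frames={n_frames} not divisible by bin width {width}; "
            "pass truncate=True to drop the remainder")
    n_bins = n_frames // width
    windows = session.activity[:, :n_bins * width].reshape(
        session.n_neurons, n_bins, width)
    X = windows.sum(axis=2) if reducer == "sum" else windows.mean(axis=2)
    mids = (np.arange(n_bins) + 0.5) * width
    labels = np.where(mids < session.injection_frame, "before", "after")
    return BinnedActivity(X, labels, bin_seconds)


def train_eval_decoder(binned: BinnedActivity, config: AnalysisConfig, rng,
                       neurons=None) -> float:
    """Accuracy of one stratified-split L1 linear SVM on the binned data."""
    X = binned.X if neurons is None else binned.X[np.asarray(neurons, dtype=int)]
    samples = X.T
    y = (binned.labels == "after").astype(int)
    if min(np.bincount(y, minlength=2)) < 2:
        raise ValueError("need at least 2 bins per epoch label")
    seed = int(rng.integers(0, 2**31 - 1))
    X_tr, X_te, y_tr, y_te = train_test_split(
        samples, y, train_size=config.train_frac, stratify=y, random_state=seed)
    if config.standardize:
        scaler = StandardScaler().fit(X_tr)
        X_tr, X_te = scaler.transform(X_tr), scaler.transform(X_te)
    clf = LinearSVC(penalty=config.svm_penalty.lower(), C=config.svm_C,
                    dual=False, max_iter=20_000)
    clf.fit(X_tr, y_tr)
    return float((clf.predict(X_te) == y_te).mean())


def _repeat_accuracies(binned: BinnedActivity, pool: np.ndarray, subset_size: int,
                       config: AnalysisConfig, rng) -> np.ndarray:
    """Mean accuracy per repeat; each repeat draws a fresh neuron subset
    (identity when the pool is already at the target size) and averages
    ``splits_per_subset`` stratified splits."""
    out = np.empty(config.subset_repeats)
    for r in range(config.subset_repeats):
        sub = (rng.choice(pool, size=subset_size, replace=False)
               if pool.size > subset_size else pool)
        out[r] = np.mean([train_eval_decoder(binned, config, rng, neurons=sub)
                          for _ in range(config.splits_per_subset)])
    return out


def decoding_pool(results: pd.DataFrame | None, n_neurons: int,
                  config: AnalysisConfig, exclude: str | None = None) -> np.ndarray:
    """Neuron indices entering the decoder.

    With ``decoding_universe="filtered"`` (default) only neurons passing the
    baseline filter are used — required so that ablation classes are defined;
    ``"all"`` uses every neuron.  ``exclude`` drops one response class.
    """
    if results is None or config.decoding_universe == "all":
        pool = np.arange(n_neurons)
        if exclude is not None:
            raise ValueError("class ablation needs a classified result table")
        return pool
    keep = results["label"] != "excluded"
    if exclude is not None:
        keep &= results["label"] != exclude
    return results.loc[keep, "neuron_id"].to_numpy(dtype=int)


def matched_population_accuracy(session_a: SessionData, session_b: SessionData,
                                config: AnalysisConfig, rng,
                                pool_a=None, pool_b=None) -> dict:
    """Neuron-count-matched population accuracies for a session pair."""
    pool_a = np.arange(session_a.n_neurons) if pool_a is None else np.asarray(pool_a, dtype=int)
    pool_b = np.arange(session_b.n_neurons) if pool_b is None else np.asarray(pool_b, dtype=int)
    n = int(min(pool_a.size, pool_b.size))
    if n < 2:
        raise ValueError(f"need at least 2 neurons on each side, got {n}")
    acc_a = _repeat_accuracies(bin_activity(session_a, config=config), pool_a, n, config, rng)
    acc_b = _repeat_accuracies(bin_activity(session_b, config=config), pool_b, n, config, rng)
    return {"n_neurons_used": n, "n_repeats": config.subset_repeats,
            "accuracy_a": float(acc_a.mean()), "accuracy_b": float(acc_b.mean()),
            "repeats_a": acc_a, "repeats_b": acc_b}


def single_neuron_accuracy(session: SessionData, config: AnalysisConfig, rng,
                           pool=None) -> dict:
    """Mean single-neuron decoder accuracy across neurons of one session."""
    pool = np.arange(session.n_neurons) if pool is None else np.asarray(pool, dtype=int)
    if pool.size < 1:
        raise ValueError("need at least 1 neuron")
    binned = bin_activity(session, config=config)
    per_neuron = np.array([
        np.mean([train_eval_decoder(binned, config, rng, neurons=[i])
                 for _ in range(config.splits_per_subset)])
        for i in pool])
    return {"mean_accuracy": float(per_neuron.mean()),
            "per_neuron": per_neuron, "n_neurons": int(pool.size)}


def ablation_accuracy(session_a: SessionData, session_b: SessionData,
                      results_a: pd.DataFrame, results_b: pd.DataFrame,
                      exclude: str, config: AnalysisConfig, rng) -> dict:
    """Count-matched accuracies after removing one response class from both sides."""
    pool_a = decoding_pool(results_a, session_a.n_neurons, config, exclude=exclude)
    pool_b = decoding_pool(results_b, session_b.n_neurons, config, exclude=exclude)
    if min(pool_a.size, pool_b.size) < 2:
        raise ValueError(
            f"ablating class {exclude!r} leaves fewer than 2 neurons")
    out = matched_population_accuracy(session_a, session_b, config, rng,
                                      pool_a=pool_a, pool_b=pool_b)
    out["excluded_class"] = exclude
    return out


def compare_accuracies(acc_a, acc_b) -> stats.StatResult:
    """Two-sided paired t-test across mice on per-mouse accuracy vectors."""
    acc_a = np.asarray(acc_a, dtype=float)
    acc_b = np.asarray(acc_b, dtype=float)
    if acc_a.size != acc_b.size:
        raise ValueError("per-mouse accuracy vectors must have equal length")
    if acc_a.size < 2:
        raise ValueError("paired comparison needs at least 2 mice")
    return stats.paired_t(acc_a, acc_b)
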