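"""Synthetic paired-session generator with known ground truth.

The generator emulates the statistical skeleton of a pre/post drug-injection
calcium-imaging experiment so that every downstream stage (response
classification, synchrony detection, cell tracking, decoding) can be tested
against planted structure without any recorded data:

* per-neuron deconvolved event trains: homogeneous Poisson events discretised
  to frames (events colliding on one frame add their amplitudes), with i.i.d.
  positive amplitude marks (gamma; exponential by default);
* a treatment effect that multiplies post-epoch event rates for planted
  "excited" and "inhibited" subpopulations while "stable" neurons keep their
  rate — applied only to non-saline sessions;
* synchronous groups built from a shared parent train whose events are copied
  (amplitude included) into member trains with a copy probability and a
  +/- 1-frame jitter;
* paired sessions sharing most cells, with centroids perturbed by small
  Gaussian jitter, for cross-session tracking.

It is a statistical stand-in, not a fluorescence forward model: there are no
dF/F traces, no indicator kinetics, and no motion artifacts.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .dataio import SessionData

CLASSES = ("excited", "inhibited", "stable")
_DECODING_BIN_SECONDS = 30.0  # default decoding bin width used for the divisibility warning


@dataclass
class GeneratorConfig:
    """Parameters of the synthetic study.

    Rates are events per second, amplitudes in arbitrary units, distances in
    micrometres.  Defaults describe a 20-min session at 10 Hz (12,000 frames)
    split in half by the injection, with base rates and amplitudes calibrated
    so most stable neurons land inside the [1000, 4000] a.u. baseline window
    used by the response stage.
    """

    n_neurons: int = 60
    frame_rate: float = 10.0
    n_frames: int = 12_000
    injection_frame: int = 6_000
    base_rate_range: tuple = (0.2, 0.6)
    amplitude_mean: float = 10.0
    amplitude_shape: float = 1.0  # gamma shape; 1 -> exponential marks
    frac_excited: float = 0.2
    frac_inhibited: float = 0.2
    effect_excited: float = 2.0
    effect_inhibited: float = 0.4
    n_sync_groups: int = 0
    sync_group_size: int = 2
    sync_parent_rate: float = 0.5
    sync_copy_prob: float = 0.8
    sync_jitter_frames: int = 1
    sync_epoch: str = "post"  # parent-train span: "post" or "full"
    centroid_field: float = 300.0
    centroid_jitter_sd: float = 1.5
    frac_shared_cells: float = 0.8
    seed: int | None = None

    def __post_init__(self):
        if self.frac_excited + self.frac_inhibited > 1:
            raise ValueError("frac_excited + frac_inhibited must be <= 1")
        lo, hi = self.base_rate_range
        if lo < 0 or hi < lo:
            raise ValueError("base_rate_range must be a nonnegative interval")
        for name in ("amplitude_mean", "amplitude_shape", "effect_excited",
                     "effect_inhibited", "sync_parent_rate", "centroid_field",
                     "centroid_jitter_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if not 0 <= self.sync_copy_prob <= 1:
            raise ValueError("sync_copy_prob must be a probability")
        if not 0 <= self.frac_shared_cells <= 1:
            raise ValueError("frac_shared_cells must be a proportion")
        if not 0 < self.injection_frame < self.n_frames:
            raise ValueError("injection_frame must split the session")
        if self.sync_epoch not in ("post", "full"):
            raise ValueError("sync_epoch must be 'post' or 'full'")


@dataclass
class GroundTruth:
    """Planted structure of one synthetic session."""

    classes: list = field(default_factory=list)  # per-neuron label in CLASSES
    sync_pairs: list = field(default_factory=list)  # list of (i, j) tuples
    identity_map: dict = field(default_factory=dict)  # session A idx -> session B idx

    def __post_init__(self):
        n = len(self.classes)
        for i, j in self.sync_pairs:
            if not (0 <= i < n and 0 <= j < n):
                raise ValueError(f"sync pair ({i}, {j}) references invalid neurons")
        vals = list(self.identity_map.values())
        if len(set(vals)) != len(vals):
            raise ValueError("identity map must be one-to-one")


@dataclass
class PairedStudy:
    """Two sessions of one mouse with shared cells and their ground truths."""

    session_a: SessionData
    session_b: SessionData
    truth_a: GroundTruth
    truth_b: GroundTruth
    identity_map: dict  # neuron index in session A -> index in session B


def _resolve_rng(config: GeneratorConfig, rng) -> np.random.Generator:
    if rng is not None:
        return rng
    return np.random.default_rng(config.seed)


def _assign_classes(config: GeneratorConfig, n: int, rng, planted: bool) -> np.ndarray:
    classes = np.full(n, "stable", dtype=object)
    if not planted:
        return classes
    n_exc = int(round(config.frac_excited * n))
    n_inh = int(round(config.frac_inhibited * n))
    order = rng.permutation(n)
    classes[order[:n_exc]] = "excited"
    classes[order[n_exc:n_exc + n_inh]] = "inhibited"
    return classes


def _event_matrix(rates_per_frame: np.ndarray, config: GeneratorConfig, rng) -> np.ndarray:
    """Draw a nonnegative activity matrix from per-neuron-per-frame rates.

    Event counts per frame are Poisson; a frame's amplitude is the sum of
    that many i.i.d. gamma marks, i.e. Gamma(count * shape, scale), which is
    exactly "amplitudes add" when Poisson thinning collides on a frame.
    """
    counts = rng.poisson(rates_per_frame)
    out = np.zeros_like(rates_per_frame)
    nz = counts > 0
    if nz.any():
        out[nz] = rng.gamma(counts[nz] * config.amplitude_shape, config.amplitude_mean)
    return out


def _pick_sync_groups(config: GeneratorConfig, classes: np.ndarray, rng) -> list:
    """Choose disjoint synchronous groups, preferring excited neurons.

    Inhibited neurons are never used (their post-epoch activity is planted
    low, so they would be removed by the synchrony activity floor anyway).
    """
    need = config.n_sync_groups * config.sync_group_size
    if need == 0:
        return []
    pool = np.flatnonzero(classes == "excited")
    if pool.size < need:
        pool = np.concatenate([pool, np.flatnonzero(classes == "stable")])
    if pool.size < need:
        raise ValueError(
            f"not enough eligible neurons ({pool.size}) for "
            f"{config.n_sync_groups} groups of {config.sync_group_size}"
        )
    chosen = rng.choice(pool, size=need, replace=False)
    return [chosen[g * config.sync_group_size:(g + 1) * config.sync_group_size]
            for g in range(config.n_sync_groups)]


def plant_synchrony(session: SessionData, group, config: GeneratorConfig,
                    rng=None) -> SessionData:
    """Superimpose shared parent events onto the trains of ``group``.

    A parent Poisson train (rate ``sync_parent_rate``) spans the post epoch
    (or the whole session with ``sync_epoch="full"``); each group member
    receives each parent event — amplitude included — with probability
    ``sync_copy_prob`` at a lag drawn uniformly from {-jitter, ..., +jitter}
    frames.  The post-epoch default mimics treatment-induced synchrony and
    leaves baseline (pre-epoch) activity untouched.  Copies falling outside
    the recording are dropped.  Returns a new SessionData; an empty group is
    a no-op.
    """
    group = np.asarray(group, dtype=int)
    if group.size == 0:
        return session
    if group.min() < 0 or group.max() >= session.n_neurons:
        raise ValueError("group references neuron indices outside the session")
    rng = _resolve_rng(config, rng)
    S = session.activity.copy()
    start = session.injection_frame if config.sync_epoch == "post" else 0
    counts = rng.poisson(config.sync_parent_rate / session.frame_rate,
                         size=session.n_frames - start)
    frames = np.repeat(np.arange(start, session.n_frames), counts)
    amps = rng.gamma(config.amplitude_shape, config.amplitude_mean, size=frames.size)
    j = config.sync_jitter_frames
    for member in group:
        take = rng.random(frames.size) < config.sync_copy_prob
        lags = rng.integers(-j, j + 1, size=frames.size) if j > 0 else np.zeros(frames.size, dtype=int)
        target = frames + lags
        ok = take & (target >= 0) & (target < session.n_frames)
        np.add.at(S[member], target[ok], amps[ok])
    return SessionData(S, session.frame_rate, session.injection_frame,
                       session.centroids, session.mouse_id, session.treatment)


def generate_session(config: GeneratorConfig, treatment: str = "saline",
                     rng=None, mouse_id: str = "m0",
                     base_rates: np.ndarray | None = None,
                     centroids: np.ndarray | None = None):
    """Generate one synthetic session and its ground truth.

    Treatment effects (rate multipliers on the post epoch) and synchronous
    groups are planted only when ``treatment`` is not "saline"; saline
    sessions are stationary and carry an all-"stable" truth, mirroring a
    vehicle injection.
    """
    rng = _resolve_rng(config, rng)
    n, F = config.n_neurons, config.n_frames
    bin_frames = _DECODING_BIN_SECONDS * config.frame_rate
    if F % int(bin_frames) != 0:
        warnings.warn(
            f"n_frames={F} is not divisible by the default decoding bin "
            f"width ({int(bin_frames)} frames); decoding will need truncation",
            stacklevel=2,
        )
    planted = treatment != "saline"
    classes = _assign_classes(config, n, rng, planted)
    if base_rates is None:
        lo, hi = config.base_rate_range
        base_rates = rng.uniform(lo, hi, size=n)
    else:
        base_rates = np.asarray(base_rates, dtype=float)
    mult = np.ones(n)
    mult[classes == "excited"] = config.effect_excited
    mult[classes == "inhibited"] = config.effect_inhibited

    lam = np.empty((n, F))
    per_frame = base_rates / config.frame_rate
    lam[:, :config.injection_frame] = per_frame[:, None]
    lam[:, config.injection_frame:] = (per_frame * mult)[:, None]
    S = _event_matrix(lam, config, rng)

    if centroids is None:
        centroids = rng.uniform(0, config.centroid_field, size=(n, 2))
    session = SessionData(S, config.frame_rate, config.injection_frame,
                          centroids, mouse_id, treatment)

    sync_pairs = []
    if planted and config.n_sync_groups > 0:
        for grp in _pick_sync_groups(config, classes, rng):
            session = plant_synchrony(session, grp, config, rng)
            grp = sorted(int(g) for g in grp)
            sync_pairs.extend(
                (grp[a], grp[b]) for a in range(len(grp)) for b in range(a + 1, len(grp))
            )
    truth = GroundTruth(classes=list(classes), sync_pairs=sync_pairs)
    session._base_rates = base_rates  # retained for calibration tests
    return session, truth


def generate_paired_sessions(config: GeneratorConfig,
                             treatments=("saline", "pitolisant"),
                             rng=None, mouse_id: str = "m0") -> PairedStudy:
    """Generate two sessions of one mouse sharing most cells.

    A fraction ``frac_shared_cells`` of neurons appears in both sessions
    (same base rate, centroid perturbed by Gaussian jitter of sd
    ``centroid_jitter_sd``); the remainder are session-unique.  The recorded
    identity map sends session-A indices to session-B indices and is
    one-to-one.  Response classes are assigned independently per session, so
    cross-session label association is null by construction.
    """
    rng = _resolve_rng(config, rng)
    n = config.n_neurons
    session_a, truth_a = generate_session(config, treatments[0], rng, mouse_id)
    rates_a = session_a._base_rates

    n_shared = int(round(config.frac_shared_cells * n))
    shared_a = rng.permutation(n)[:n_shared]
    order_b = rng.permutation(n)  # slot in B for shared cells, then new cells
    lo, hi = config.base_rate_range
    rates_b = rng.uniform(lo, hi, size=n)
    cent_b = rng.uniform(0, config.centroid_field, size=(n, 2))
    identity = {}
    for slot, a_idx in enumerate(shared_a):
        b_idx = int(order_b[slot])
        identity[int(a_idx)] = b_idx
        rates_b[b_idx] = rates_a[a_idx]
        cent_b[b_idx] = session_a.centroids[a_idx] + rng.normal(
            0, config.centroid_jitter_sd, size=2)
    session_b, truth_b = generate_session(
        config, treatments[1], rng, mouse_id, base_rates=rates_b, centroids=cent_b)
    truth_a.identity_map = identity
    return PairedStudy(session_a, session_b, truth_a, truth_b, identity)


def ground_truth_to_json(truth: GroundTruth) -> dict:
    return {
        "classes": list(truth.classes),
        "sync_pairs": [[int(i), int(j)] for i, j in truth.sync_pairs],
        "identity_map": {str(k): int(v) for k, v in truth.identity_map.items()},
    }


def ground_truth_from_json(d: dict) -> GroundTruth:
    return GroundTruth(
        classes=list(d.get("classes", [])),
        sync_pairs=[tuple(p) for p in d.get("sync_pairs", [])],
        identity_map={int(k): int(v) for k, v in d.get("identity_map", {}).items()},
    )
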