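"""Session containers, analysis configuration, and file I/O.

A recording session is a neurons x frames matrix of deconvolved calcium
activity (nonnegative amplitudes, arbitrary units, approximately
proportional to firing rate), split by the injection frame into a
pre-injection and a post-injection epoch.  Epochs are half-open frame
ranges: pre = [0, injection_frame), post = [injection_frame, n_frames).

On disk a session is an HDF5 container (dataset ``/S`` for the activity
matrix, ``/centroids`` for ROI centre coordinates in micrometres, session
metadata as root attributes) plus optional CSV centroid tables.  Analysis
configuration is a flat YAML mapping; omitted keys fall back to the
published defaults and unknown keys are rejected so typos cannot silently
change thresholds.
"""
from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from .utils import jsonify

TREATMENTS = ("saline", "pitolisant", "other")


class ConfigError(ValueError):
    """Invalid or unknown analysis-configuration keys/values."""


class SchemaError(ValueError):
    """Session container does not match the expected on-disk schema."""


class ValidationError(ValueError):
    """Session content violates an invariant (e.g. negative activity)."""


@dataclass
class SessionData:
    """One imaging session: activity matrix, geometry and metadata.

    Attributes
    ----------
    activity : (n_neurons, n_frames) float array, entries >= 0
        Deconvolved per-frame amplitudes (a.u.).
    frame_rate : float
        Acquisition rate in Hz.
    injection_frame : int
        Frame index splitting the pre and post epochs; 0 < idx < n_frames.
    centroids : (n_neurons, 2) float array
        ROI centroid (x, y) in micrometres.
    mouse_id, treatment : str
        Session metadata; treatment is "saline", "pitolisant" or "other".
    """

    activity: np.ndarray
    frame_rate: float
    injection_frame: int
    centroids: np.ndarray
    mouse_id: str = "m0"
    treatment: str = "saline"

    def __post_init__(self):
        self.activity = np.asarray(self.activity, dtype=np.float64)
        self.centroids = np.asarray(self.centroids, dtype=np.float64)
        self.injection_frame = int(self.injection_frame)
        self.validate()

    def validate(self) -> None:
        if self.activity.ndim != 2:
            raise ValidationError("activity must be a neurons x frames matrix")
        neg = np.argwhere(self.activity < 0)
        if neg.size:
            i, t = neg[0]
            raise ValidationError(
                f"negative activity value {self.activity[i, t]!r} at neuron {i}, frame {t}"
            )
        if not 0 < self.injection_frame < self.n_frames:
            raise ValidationError(
                f"injection_frame {self.injection_frame} outside (0, {self.n_frames})"
            )
        if self.centroids.shape != (self.n_neurons, 2):
            raise ValidationError(
                f"centroids shape {self.centroids.shape} != ({self.n_neurons}, 2)"
            )
        if self.treatment not in TREATMENTS:
            raise ValidationError(f"treatment must be one of {TREATMENTS}")

    @property
    def n_neurons(self) -> int:
        return self.activity.shape[0]

    @property
    def n_frames(self) -> int:
        return self.activity.shape[1]

    @property
    def pre(self) -> np.ndarray:
        """Activity over the pre-injection epoch (view)."""
        return self.activity[:, : self.injection_frame]

    @property
    def post(self) -> np.ndarray:
        """Activity over the post-injection epoch (view)."""
        return self.activity[:, self.injection_frame:]


@dataclass
class AnalysisConfig:
    """All thresholds and iteration counts of the analysis, with published defaults.

    Units: activity totals in a.u., distances in micrometres, bins in seconds.

    a_before_lo / a_before_hi
        Inclusive baseline-activity window [1000, 4000] a.u.; neurons whose
        pre-epoch total falls outside are excluded from response
        classification.
    score_null_iters / score_tail
        Temporal-shuffle iterations (100,000) and tail mass (0.1%) for the
        activity-score null.
    ccg_null_iters / ccg_tail / ccg_activity_min
        Shuffle iterations (10,000), tail (top 1%) and the post-epoch
        activity floor (3000 a.u.) for synchrony analysis.
    track_max_dist_um
        Centroid distance below which two cells are the same neuron (6.5 um,
        strict).
    bin_seconds / train_frac / subset_repeats / svm_penalty / svm_C
        Decoding design: 30-s bins, 70/30 stratified split, 100 repeats of
        neuron-count-matched subsetting, L1-penalised linear SVM.
    """

    a_before_lo: float = 1000.0
    a_before_hi: float = 4000.0
    score_null_iters: int = 100_000
    score_tail: float = 0.001
    event_epoch_minutes: float = 10.0
    ccg_null_iters: int = 10_000
    ccg_tail: float = 0.01
    ccg_activity_min: float = 3000.0
    track_max_dist_um: float = 6.5
    bin_seconds: float = 30.0
    train_frac: float = 0.7
    subset_repeats: int = 100
    svm_penalty: str = "L1"
    svm_C: float = 1.0
    splits_per_subset: int = 1
    seed: int = 0
    # implementation choices exposed as configuration
    shuffle_scheme: str = "permutation"  # or "circular"
    ccg_epoch: str = "post"  # or "pre"
    bin_reducer: str = "sum"  # or "mean"
    standardize: bool = True
    decoding_universe: str = "filtered"  # or "all"
    event_size_level: str = "event"  # or "neuron_mean"
    adjacent_saline: str = "second"  # or "first"

    def __post_init__(self):
        for name in ("score_tail", "ccg_tail"):
            v = getattr(self, name)
            if not 0 < v < 0.5:
                raise ConfigError(f"{name} must lie in (0, 0.5), got {v}")
        if not 0 < self.train_frac < 1:
            raise ConfigError(f"train_frac must lie in (0, 1), got {self.train_frac}")
        for name in ("score_null_iters", "ccg_null_iters", "subset_repeats",
                     "splits_per_subset"):
            if getattr(self, name) < 1:
                raise ConfigError(f"{name} must be a positive count")
        if self.a_before_lo >= self.a_before_hi:
            raise ConfigError("a_before_lo must be < a_before_hi")
        if self.svm_penalty.lower() not in ("l1", "l2"):
            raise ConfigError("svm_penalty must be 'L1' or 'L2'")
        if self.shuffle_scheme not in ("permutation", "circular"):
            raise ConfigError("shuffle_scheme must be 'permutation' or 'circular'")

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = sorted(set(d) - known)
        if unknown:
            raise ConfigError(f"unknown configuration keys: {unknown}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        if not isinstance(d, dict):
            raise ConfigError("configuration file must contain a mapping")
        return cls.from_dict(d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    def replace(self, **kwargs) -> "AnalysisConfig":
        return dataclasses.replace(self, **kwargs)

    @classmethod
    def fast(cls, **kwargs) -> "AnalysisConfig":
        """Desk-scale preset: reduced shuffle/repeat counts for quick runs.

        The published iteration counts remain the defaults; this preset
        trades tail-quantile resolution for runtime (the strict-exceedance
        decision rule keeps the nominal type-I rate at any iteration count).
        """
        base = dict(score_null_iters=2000, ccg_null_iters=1000, subset_repeats=20)
        base.update(kwargs)
        return cls(**base)


# ---------------------------------------------------------------------------
# session containers


def write_session(session: SessionData, path) -> None:
    """Write a session to an HDF5 container (lossless, uncompressed)."""
    with h5py.File(path, "w") as fh:
        fh.create_dataset("S", data=session.activity)
        fh.create_dataset("centroids", data=session.centroids)
        fh.attrs["frame_rate"] = session.frame_rate
        fh.attrs["injection_frame"] = session.injection_frame
        fh.attrs["mouse_id"] = session.mouse_id
        fh.attrs["treatment"] = session.treatment


def read_session(path) -> SessionData:
    """Read and validate a session container; rejects negative activity."""
    with h5py.File(path, "r") as fh:
        for name in ("S", "centroids"):
            if name not in fh:
                raise SchemaError(f"{path}: missing dataset '/{name}'")
        for attr in ("frame_rate", "injection_frame", "mouse_id", "treatment"):
            if attr not in fh.attrs:
                raise SchemaError(f"{path}: missing attribute '{attr}'")
        return SessionData(
            activity=fh["S"][()],
            centroids=fh["centroids"][()],
            frame_rate=float(fh.attrs["frame_rate"]),
            injection_frame=int(fh.attrs["injection_frame"]),
            mouse_id=str(fh.attrs["mouse_id"]),
            treatment=str(fh.attrs["treatment"]),
        )


def write_centroids_csv(session: SessionData, path) -> None:
    df = pd.DataFrame({
        "neuron_id": np.arange(session.n_neurons),
        "x_um": session.centroids[:, 0],
        "y_um": session.centroids[:, 1],
    })
    df.to_csv(path, index=False)


def read_centroids_csv(path) -> np.ndarray:
    df = pd.read_csv(path)
    for col in ("x_um", "y_um"):
        if col not in df.columns:
            raise SchemaError(f"{path}: missing column '{col}'")
    if "neuron_id" in df.columns:
        df = df.sort_values("neuron_id")
    return df[["x_um", "y_um"]].to_numpy(dtype=float)


# ---------------------------------------------------------------------------
# reports


def write_report(report: dict, out_dir, tables: dict | None = None) -> Path:
    """Write a machine-readable JSON summary plus human-readable CSV tables.

    ``tables`` maps a base name to a DataFrame (per-neuron scores/classes,
    per-pair synchrony, per-mouse accuracies ...).  The JSON is serialised
    with sorted keys so identical inputs produce byte-identical files.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    path = out_dir / "report.json"
    path.write_text(report_to_json(report))
    for name, df in (tables or {}).items():
        df.to_csv(out_dir / f"{name}.csv", index=False)
    return path


def report_to_json(report: dict) -> str:
    return json.dumps(jsonify(report), sort_keys=True, indent=2) + "\n"
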