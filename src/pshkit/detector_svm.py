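"""Support-vector-machine PSH episode detector.

The machine-learning counterpart of the rule-based detector: summary
statistics (mean, standard deviation, minimum, maximum, median) of
heart rate are extracted from 10-minute rolling windows with a
2.5-minute step (75 % overlap — the larger step limits redundancy in
the training set).  Windows fully inside a clinician-annotated episode
are labelled positive, windows disjoint from every episode negative,
and windows straddling an episode boundary are excluded from training
(partial-overlap windows belong to neither the episode nor the
baseline regime).  Features are standardised and fed to an SVM with a
radial-basis-function kernel.

At prediction time the model labels rolling windows of unseen
heart-rate data with its training geometry and fuses window labels to
per-sample labels by the same max rule the expert system uses.
Episode assembly and merging then proceed identically.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import joblib
import numpy as np
from sklearn.svm import SVC

from .episodes import EpisodeSet, assemble_episodes, merge_episodes
from .signal_model import (
    PointLabelSeries,
    SignalError,
    VitalSignSeries,
    fuse_window_votes,
    rolling_window_stats,
)

logger = logging.getLogger(__name__)

MODEL_FORMAT_VERSION = 1
FEATURE_NAMES = ("mean", "sd", "min", "max", "median")


class TrainingDataError(SignalError):
    """The training set lacks a class or is otherwise unusable."""


@dataclass(frozen=True)
class FeatureVector:
    """Summary-statistic features of one rolling heart-rate window."""

    start_s: float
    end_s: float
    mean: float
    sd: float
    min: float
    max: float
    median: float

    def as_array(self) -> np.ndarray:
        return np.array([self.mean, self.sd, self.min, self.max, self.median])


@dataclass(frozen=True)
class TrainingSet:
    """Labelled window features: X (n, 5), y binary, and class counts."""

    X: np.ndarray
    y: np.ndarray
    windows: tuple[tuple[float, float], ...]
    n_positive: int
    n_negative: int


@dataclass(frozen=True)
class Hyperparams:
    """SVC hyperparameters; the ecosystem defaults unless overridden."""

    C: float = 1.0
    gamma: float | str = "scale"
    class_weight: dict | str | None = None


@dataclass
class DetectorModel:
    """Trained RBF-SVM window classifier plus its preprocessing state.

    Stores the per-feature standardisation offsets/scales learned from
    the training data and the window geometry the features were
    extracted with, so prediction always matches the training feature
    distribution.  Serialises to a versioned joblib archive that
    reloads to identical predictions.
    """

    svc: SVC
    feature_offset: np.ndarray
    feature_scale: np.ndarray
    window_s: float
    step_s: float
    seed: int
    hyperparams: Hyperparams

    def standardize(self, X: np.ndarray) -> np.ndarray:
        return (X - self.feature_offset) / self.feature_scale

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.svc.predict(self.standardize(X)).astype(np.int8)

    def save(self, path: str | Path) -> None:
        payload = {
            "format_version": MODEL_FORMAT_VERSION,
            "feature_names": FEATURE_NAMES,
            "svc": self.svc,
            "feature_offset": self.feature_offset,
            "feature_scale": self.feature_scale,
            "window_s": self.window_s,
            "step_s": self.step_s,
            "seed": self.seed,
            "hyperparams": self.hyperparams,
        }
        joblib.dump(payload, path)

    @classmethod
    def load(cls, path: str | Path) -> "DetectorModel":
        payload = joblib.load(path)
        version = payload.get("format_version")
        if version != MODEL_FORMAT_VERSION:
            raise SignalError(f"unsupported model format version {version!r}")
        return cls(
            svc=payload["svc"],
            feature_offset=payload["feature_offset"],
            feature_scale=payload["feature_scale"],
            window_s=payload["window_s"],
            step_s=payload["step_s"],
            seed=payload["seed"],
            hyperparams=payload["hyperparams"],
        )


# ---------------------------------------------------------------------------
# Feature extraction and training-set construction
# ---------------------------------------------------------------------------

def extract_features(
    hr: VitalSignSeries, window_s: float = 600.0, step_s: float = 150.0
) -> list[FeatureVector]:
    """One feature vector per non-empty rolling window (empty windows skipped)."""
    if step_s <= 0:
        raise SignalError("step_s must be positive")
    rs = rolling_window_stats(hr, window_s, step_s)
    return [
        FeatureVector(
            start_s=float(rs.starts[k]),
            end_s=float(rs.ends[k]),
            mean=float(rs.mean[k]),
            sd=float(rs.sd[k]),
            min=float(rs.min[k]),
            max=float(rs.max[k]),
            median=float(rs.median[k]),
        )
        for k in range(len(rs))
        if rs.n[k] > 0
    ]


def feature_matrix(features: list[FeatureVector]) -> np.ndarray:
    if not features:
        return np.empty((0, len(FEATURE_NAMES)))
    return np.stack([f.as_array() for f in features])


def _window_label(start: float, end: float, episodes: EpisodeSet) -> int | None:
    """1 if fully inside an episode, 0 if disjoint from all, None if straddling."""
    for a, b in episodes.intervals:
        if start >= a and end <= b:
            return 1
        if start < b and end > a:
            return None
    return 0


def build_training_set(
    hr: VitalSignSeries,
    annotations: EpisodeSet,
    window_s: float = 600.0,
    step_s: float = 150.0,
) -> TrainingSet:
    """Label rolling-window features from annotated episodes.

    Positive: window fully contained in some annotated episode.
    Negative: window disjoint from every episode (inter-episode
    baseline).  Boundary-straddling windows are excluded.
    """
    features = extract_features(hr, window_s, step_s)
    kept_X, kept_y, kept_w = [], [], []
    for f in features:
        lab = _window_label(f.start_s, f.end_s, annotations)
        if lab is None:
            continue
        kept_X.append(f.as_array())
        kept_y.append(lab)
        kept_w.append((f.start_s, f.end_s))
    y = np.array(kept_y, dtype=np.int8)
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0:
        raise TrainingDataError("no positive training windows (no window fully inside an episode)")
    if n_neg == 0:
        raise TrainingDataError("no negative training windows (no window disjoint from all episodes)")
    return TrainingSet(
        X=np.stack(kept_X), y=y, windows=tuple(kept_w), n_positive=n_pos, n_negative=n_neg
    )


# ---------------------------------------------------------------------------
# Training and prediction
# ---------------------------------------------------------------------------

def train_detector(
    training: TrainingSet,
    hyperparams: Hyperparams | None = None,
    seed: int = 0,
    window_s: float = 600.0,
    step_s: float = 150.0,
) -> DetectorModel:
    """Standardise features and fit the RBF-kernel SVM.

    Deterministic given the seed and training-data order.  A feature
    with zero variance across the training set gets unit scale (with a
    warning) rather than dividing by zero.
    """
    hyperparams = hyperparams or Hyperparams()
    offset = training.X.mean(axis=0)
    scale = training.X.std(axis=0)
    degenerate = scale == 0.0
    if degenerate.any():
        names = [FEATURE_NAMES[i] for i in np.nonzero(degenerate)[0]]
        warnings.warn(f"zero-variance feature(s) {names}: standardisation scale set to 1", stacklevel=2)
        scale = np.where(degenerate, 1.0, scale)
    svc = SVC(
        C=hyperparams.C,
        kernel="rbf",
        gamma=hyperparams.gamma,
        class_weight=hyperparams.class_weight,
        random_state=seed,
    )
    svc.fit((training.X - offset) / scale, training.y)
    return DetectorModel(
        svc=svc,
        feature_offset=offset,
        feature_scale=scale,
        window_s=window_s,
        step_s=step_s,
        seed=seed,
        hyperparams=hyperparams,
    )


def label_points_svm(hr: VitalSignSeries, model: DetectorModel) -> PointLabelSeries:
    """Per-sample labels: max-fusion of window predictions (training geometry)."""
    if len(hr) == 0:
        return PointLabelSeries(hr.timestamps, np.zeros(0, dtype=np.int8), hr.nominal_rate_hz)
    rs = rolling_window_stats(hr, model.window_s, model.step_s)
    nonempty = rs.n > 0
    positive = np.zeros(len(rs), dtype=bool)
    if nonempty.any():
        X = np.column_stack(
            [rs.mean[nonempty], rs.sd[nonempty], rs.min[nonempty], rs.max[nonempty], rs.median[nonempty]]
        )
        positive[nonempty] = model.predict(X) == 1
    labels = fuse_window_votes(len(hr), rs.lo, rs.hi, positive)
    return PointLabelSeries(hr.timestamps, labels, hr.nominal_rate_hz)


def detect_episodes_svm(
    hr: VitalSignSeries,
    model: DetectorModel,
    merge_gap_s: float = 60.0,
    max_sample_gap_s: float = 60.0,
) -> EpisodeSet:
    """End-to-end SVM detection: predict windows, fuse, assemble, merge."""
    labels = label_points_svm(hr, model)
    eps = assemble_episodes(labels, hr.patient_id, source="svm", max_sample_gap_s=max_sample_gap_s)
    return merge_episodes(eps, min_gap_s=merge_gap_s)
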