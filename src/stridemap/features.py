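"""Per-stride feature extraction and min-max scaling.

Each stride window is reduced to a 10-element vector: minimum, maximum, mean,
standard deviation and range of the shank and thigh sagittal inclination over
the window.  These are the channels and statistics that survived correlation
screening against the activity targets; gyroscope and acceleration channels
are ingested and stored but do not enter the vector.

The scaler maps every feature onto the unit interval using the training-fold
minimum and maximum.  It is always fitted on training data only and applied
unchanged to test data; out-of-range test values are NOT clipped (they map
below 0 or above 1), and a degenerate constant training column maps every
input to 0.  Standard deviation uses the population convention (divide by n).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from .errors import InvalidInputError
from .gait import StepWindow
from .recording import InertialRecording

STATS = ("min", "max", "mean", "std", "range")

#: Fixed order of the 10 features.
FEATURE_NAMES = [f"{sensor}_{stat}" for sensor in ("shank", "thigh") for stat in STATS]


def extract_features(recording: InertialRecording, window: StepWindow) -> np.ndarray:
    """10-element feature vector for one stride window (fixed FEATURE_NAMES order)."""
    if window.start_index < 0 or window.end_index > len(recording):
        raise InvalidInputError("window indices outside the recording")
    if window.end_index - window.start_index < 2:
        raise InvalidInputError("window must span at least 2 samples")
    values = []
    for sensor in ("shank", "thigh"):
        seg = recording.inclination(sensor)[window.start_index : window.end_index]
        mn, mx = float(np.min(seg)), float(np.max(seg))
        values.extend([mn, mx, float(np.mean(seg)), float(np.std(seg)), mx - mn])
    return np.array(values)


def extract_feature_matrix(recording: InertialRecording, windows: Iterable[StepWindow]) -> np.ndarray:
    windows = list(windows)
    if not windows:
        return np.empty((0, len(FEATURE_NAMES)))
    return np.vstack([extract_features(recording, w) for w in windows])


@dataclass(frozen=True)
class ScalerParams:
    """Per-feature training minimum and maximum."""

    minimum: np.ndarray
    maximum: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "minimum", np.asarray(self.minimum, dtype=float))
        object.__setattr__(self, "maximum", np.asarray(self.maximum, dtype=float))
        if self.minimum.shape != self.maximum.shape:
            raise InvalidInputError("minimum and maximum must have the same shape")
        if np.any(self.maximum < self.minimum):
            raise InvalidInputError("per-feature maximum must be >= minimum")


def fit_scaler(training_features: np.ndarray) -> ScalerParams:
    """Column-wise min/max of the training matrix."""
    X = np.asarray(training_features, dtype=float)
    if X.ndim == 1:
        X = X.reshape(1, -1)
    if X.size == 0:
        raise InvalidInputError("cannot fit a scaler on an empty matrix")
    return ScalerParams(minimum=X.min(axis=0), maximum=X.max(axis=0))


def apply_scaler(params: ScalerParams, features: np.ndarray) -> np.ndarray:
    """x -> (x - min) / (max - min) per feature; degenerate columns map to 0."""
    X = np.asarray(features, dtype=float)
    span = params.maximum - params.minimum
    safe = np.where(span > 0, span, 1.0)
    scaled = (X - params.minimum) / safe
    return np.where(span > 0, scaled, 0.0)


def features_to_frame(X: np.ndarray, labels=None, subject_ids=None, trial_ids=None) -> pd.DataFrame:
    """Feature matrix as a DataFrame with the fixed 10-column header plus metadata."""
    df = pd.DataFrame(np.asarray(X, dtype=float), columns=FEATURE_NAMES)
    if labels is not None:
        df["label"] = [getattr(l, "value", l) for l in labels]
    if subject_ids is not None:
        df["subject_id"] = list(subject_ids)
    if trial_ids is not None:
        df["trial_id"] = list(trial_ids)
    return df
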