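"""Gait-cycle segmentation from the thigh pitch angle.

Step events are local maxima of the thigh sagittal inclination: at maximum
thigh pitch the heel is about to strike the ground, which marks the start of
a stride.  Detection uses :func:`scipy.signal.find_peaks` with a height
threshold of 1.6 rad, prominence 0.2 rad and a minimum separation of 16
samples.  Successive events closer together than the maximum cycle duration
(2 s) bound one stride window; longer gaps are treated as standing and
produce no window.  One "step" here is a full stride of the instrumented leg.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Sequence

import numpy as np
from scipy.signal import find_peaks

from .errors import InvalidInputError
from .recording import InertialRecording


@dataclass(frozen=True)
class StepDetectorConfig:
    """Peak-detection thresholds; defaults are the deployed values.

    min_separation is deliberately expressed in samples (at the nominal 30 Hz
    it corresponds to ~0.53 s); override it when running at other rates.
    """

    prominence: float = 0.2  # rad
    min_height: float = 1.6  # rad
    min_separation: int = 16  # samples
    max_cycle_duration: float = 2.0  # s

    def __post_init__(self):
        if not (self.prominence > 0 and self.min_height > 0 and self.min_separation > 0 and self.max_cycle_duration > 0):
            raise InvalidInputError("all StepDetectorConfig fields must be strictly positive")


@dataclass(frozen=True)
class StepWindow:
    """Half-open stride window [start_index, end_index) between two step events."""

    start_index: int
    end_index: int
    start_time: float
    end_time: float

    def __post_init__(self):
        if self.end_index <= self.start_index:
            raise InvalidInputError("window must contain at least one sample")

    @property
    def duration(self) -> float:
        return self.end_time - self.start_time

    @property
    def midpoint_time(self) -> float:
        return 0.5 * (self.start_time + self.end_time)


def detect_step_events(recording: InertialRecording, config: StepDetectorConfig = StepDetectorConfig()) -> np.ndarray:
    """Indices of step events (thigh-pitch maxima) in a recording.

    Plateaus of equal consecutive maxima yield their first sample, which keeps
    detection deterministic on quantised signals.
    """
    if len(recording) < 2:
        raise InvalidInputError("recording shorter than 2 samples")
    signal = recording.inclination("thigh")
    _, props = find_peaks(
        signal,
        height=config.min_height,
        prominence=config.prominence,
        distance=config.min_separation,
        plateau_size=(1, None),
    )
    return props["left_edges"].astype(int)


def segment_steps(
    events: Sequence[int],
    timestamps: np.ndarray,
    config: StepDetectorConfig = StepDetectorConfig(),
) -> List[StepWindow]:
    """Cut stride windows between consecutive step events.

    Every period between two detected events shorter than the maximum cycle
    duration is assumed to be one stride; longer gaps (standing) are dropped.
    """
    events = np.asarray(events, dtype=int)
    timestamps = np.asarray(timestamps, dtype=float)
    if events.size and (np.any(np.diff(events) <= 0)):
        raise InvalidInputError("events must be strictly increasing")
    if events.size and (events[0] < 0 or events[-1] >= len(timestamps)):
        raise InvalidInputError("event index outside the recording")
    windows: List[StepWindow] = []
    for a, b in zip(events[:-1], events[1:]):
        t0, t1 = timestamps[a], timestamps[b]
        if t1 - t0 < config.max_cycle_duration:
            windows.append(StepWindow(int(a), int(b), float(t0), float(t1)))
    return windows


def detect_and_segment(recording: InertialRecording, config: StepDetectorConfig = StepDetectorConfig()) -> List[StepWindow]:
    """Convenience wrapper: detect events, then segment stride windows."""
    events = detect_step_events(recording, config)
    return segment_steps(events, recording.timestamps, config)
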