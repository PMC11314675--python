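"""Two-sensor IMU trial container and its CSV trial format.

A trial is one continuous recording from two IMUs mounted on the thigh and
shank of the instrumented leg.  Each sensor delivers the sagittal-plane
inclination (pitch, radians), a 3-axis angular velocity (rad/s) and a 3-axis
acceleration (m/s^2) at a nominal ~30 Hz.  Only the inclination channels feed
the activity classifier; the other channels are carried so the on-disk trial
format is complete.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InvalidInputError

SENSORS = ("thigh", "shank")

#: Column order of the CSV trial format (one file per trial, '.' decimals).
TRIAL_COLUMNS = ["time_s"] + [
    f"{sensor}_{ch}"
    for sensor in SENSORS
    for ch in ("incl", "gx", "gy", "gz", "ax", "ay", "az")
]


@dataclass
class SensorChannels:
    """Channels of one IMU: inclination (N,), gyro (N,3), accel (N,3)."""

    inclination: np.ndarray
    angular_velocity: np.ndarray
    acceleration: np.ndarray

    def __post_init__(self):
        self.inclination = np.asarray(self.inclination, dtype=float)
        self.angular_velocity = np.asarray(self.angular_velocity, dtype=float).reshape(-1, 3)
        self.acceleration = np.asarray(self.acceleration, dtype=float).reshape(-1, 3)


@dataclass
class InertialRecording:
    """One trial of two-sensor IMU data with a strictly increasing time base."""

    timestamps: np.ndarray
    thigh: SensorChannels
    shank: SensorChannels
    subject_id: str = "S0"
    trial_id: str = "T0"

    def __post_init__(self):
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        n = len(self.timestamps)
        if n < 2:
            raise InvalidInputError("a recording needs at least 2 samples")
        if np.any(np.diff(self.timestamps) <= 0):
            raise InvalidInputError("timestamps must be strictly increasing")
        for name in SENSORS:
            ch: SensorChannels = getattr(self, name)
            if not (len(ch.inclination) == len(ch.angular_velocity) == len(ch.acceleration) == n):
                raise InvalidInputError(f"{name} channels must match the number of timestamps")

    def __len__(self) -> int:
        return len(self.timestamps)

    def inclination(self, sensor: str) -> np.ndarray:
        if sensor not in SENSORS:
            raise InvalidInputError(f"unknown sensor {sensor!r}")
        return getattr(self, sensor).inclination

    # -- CSV trial format ---------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        cols = {"time_s": self.timestamps}
        for sensor in SENSORS:
            ch: SensorChannels = getattr(self, sensor)
            cols[f"{sensor}_incl"] = ch.inclination
            for i, ax in enumerate("xyz"):
                cols[f"{sensor}_g{ax}"] = ch.angular_velocity[:, i]
            for i, ax in enumerate("xyz"):
                cols[f"{sensor}_a{ax}"] = ch.acceleration[:, i]
        return pd.DataFrame(cols)[TRIAL_COLUMNS]

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, subject_id: str = "S0", trial_id: str = "T0") -> "InertialRecording":
        df = pd.read_csv(path)
        missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
        if missing:
            raise InvalidInputError(f"trial CSV missing columns: {missing}")
        sensors = {}
        for sensor in SENSORS:
            sensors[sensor] = SensorChannels(
                inclination=df[f"{sensor}_incl"].to_numpy(),
                angular_velocity=df[[f"{sensor}_g{ax}" for ax in "xyz"]].to_numpy(),
                acceleration=df[[f"{sensor}_a{ax}" for ax in "xyz"]].to_numpy(),
            )
        return cls(
            timestamps=df["time_s"].to_numpy(),
            thigh=sensors["thigh"],
            shank=sensors["shank"],
            subject_id=subject_id,
            trial_id=trial_id,
        )
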