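"""Synthetic gait recordings, ground-truth networks and noisy GPS traces.

The generators exist so the whole pipeline — stride detection, feature
extraction, classifier protocols, georeferencing and map construction — can
be exercised end to end without access to a recorded IMU/GPS study dataset.

Gait signals are rectified sinusoids: the thigh pitch of one stride of
period T is A*|sin(pi*t/T)|, with class-conditional amplitude and period and
the peak (the heel-strike marker) always above the 1.6 rad detection
threshold.  The shank channel differs between classes in offset, amplitude
and phase so the feature vector separates the three activities.  Per-subject
variability multiplies amplitudes; additive Gaussian noise models sensor
noise.  Gyroscope channels carry the waveform's derivative and acceleration
channels its second derivative (plus noise): they complete the trial format
but, like in the deployed feature set, are not used by the classifier.

GPS traces are sampled along a route through a known network at walking
speed, with isotropic Gaussian position noise and, optionally, a contiguous
run of fixes displaced by a constant offset — the signature of a multipath
reflection near a tall building.

All generators are pure functions of their parameters and seed.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .errors import InvalidInputError
from .gait import StepDetectorConfig, detect_step_events, segment_steps
from .features import extract_features
from .geo import LocalFrame, point_at_arc, polyline_arclength
from .georef import GeoFix
from .har import ActivityClass, LabeledSample
from .pathmodel import Crossing, MapStore, PathRecord
from .recording import InertialRecording, SensorChannels

#: Reference location of the generated networks (lon, lat).
BASE_LON, BASE_LAT = 10.0715, 48.8390


@dataclass(frozen=True)
class ClassWaveform:
    """Waveform parameters of one activity class."""

    stride_period: float  # s
    thigh_amplitude: float  # rad, peak of the rectified sinusoid
    shank_amplitude: float  # rad
    shank_offset: float  # rad
    shank_phase: float  # rad


@dataclass(frozen=True)
class GaitGeneratorParams:
    """Study conditions for the gait generator.

    Thigh peak amplitudes all clear the 1.6 rad detection threshold by more
    than 3 * noise_sd; the per-subject amplitude factor is floored so that
    margin survives subject variability.
    """

    sampling_rate: float = 30.0  # Hz
    waveforms: Dict[ActivityClass, ClassWaveform] = field(
        default_factory=lambda: {
            ActivityClass.WALK: ClassWaveform(1.1, 1.8, 1.0, 0.0, 0.0),
            ActivityClass.STAIRS_UP: ClassWaveform(1.4, 2.1, 1.2, 0.45, 0.5),
            ActivityClass.STAIRS_DOWN: ClassWaveform(1.2, 1.9, 0.85, -0.45, -0.5),
        }
    )
    noise_sd: float = 0.05  # rad
    subject_variability_sd: float = 0.08  # multiplicative on amplitudes
    bout_gap: float = 3.0  # s of low-angle standing between bouts (> max cycle duration)
    seed: int = 0

    def __post_init__(self):
        if self.sampling_rate <= 0:
            raise InvalidInputError("sampling_rate must be positive")
        for wf in self.waveforms.values():
            if wf.stride_period <= 0 or wf.thigh_amplitude <= 0:
                raise InvalidInputError("periods and amplitudes must be positive")
            if wf.thigh_amplitude <= 1.6 + 3 * self.noise_sd:
                raise InvalidInputError("thigh amplitude must clear 1.6 rad + 3*noise_sd")


@dataclass(frozen=True)
class TraceGeneratorParams:
    """Study conditions for the GPS trace generator."""

    fix_interval: float = 1.0  # s
    position_noise_sd: float = 2.0  # m
    reflection_probability: float = 0.05  # per trace
    reflection_offset: float = 25.0  # m
    walking_speed: float = 1.3  # m/s
    seed: int = 0

    def __post_init__(self):
        for name in ("fix_interval", "position_noise_sd", "reflection_probability", "reflection_offset", "walking_speed"):
            if getattr(self, name) < 0:
                raise InvalidInputError(f"{name} must be non-negative")


def _subject_rng(seed: int, subject_id: str, trial_id: str = "") -> np.random.Generator:
    tag = zlib.crc32(f"{subject_id}/{trial_id}".encode())
    return np.random.default_rng([seed, tag])


#: (start_time, end_time, label) ground-truth span of one activity bout.
Span = Tuple[float, float, ActivityClass]


def generate_gait_recording(
    activity_schedule: Sequence[Tuple[ActivityClass, int]],
    params: GaitGeneratorParams = GaitGeneratorParams(),
    subject_id: str = "S0",
    trial_id: str = "T0",
) -> Tuple[InertialRecording, List[Span]]:
    """Generate one trial following a bout schedule [(class, n_strides), ...].

    Bouts are separated by a standing gap longer than the maximum cycle
    duration, so stride windows never straddle two activities.  Returns the
    recording and the ground-truth bout spans.
    """
    if not activity_schedule:
        raise InvalidInputError("activity schedule must be non-empty")
    rng = _subject_rng(params.seed, subject_id, trial_id)
    factor = 1.0 + params.subject_variability_sd * float(rng.standard_normal())
    # keep the heel-strike peak detectable for every subject
    amp_floor = 1.6 + 3 * params.noise_sd + 0.02
    dt = 1.0 / params.sampling_rate
    rest_level = 0.2  # rad, thigh pitch while standing

    t_chunks: List[np.ndarray] = []
    thigh_chunks: List[np.ndarray] = []
    shank_chunks: List[np.ndarray] = []
    spans: List[Span] = []
    t0 = 0.0

    def standing(duration: float, start: float):
        n = max(int(round(duration * params.sampling_rate)), 1)
        tt = start + dt * np.arange(n)
        t_chunks.append(tt)
        thigh_chunks.append(np.full(n, rest_level))
        shank_chunks.append(np.full(n, rest_level))
        return start + n * dt

    t0 = standing(1.0, t0)
    for bout_index, (activity, n_strides) in enumerate(activity_schedule):
        activity = ActivityClass(activity)
        if n_strides < 1:
            raise InvalidInputError("each bout needs at least one stride")
        wf = params.waveforms[activity]
        thigh_amp = max(wf.thigh_amplitude * factor, amp_floor)
        shank_amp = wf.shank_amplitude * factor
        duration = n_strides * wf.stride_period
        n = int(round(duration * params.sampling_rate))
        tt = t0 + dt * np.arange(n)
        phase = np.pi * (tt - t0) / wf.stride_period
        thigh_chunks.append(thigh_amp * np.abs(np.sin(phase)))
        shank_chunks.append(wf.shank_offset + shank_amp * np.abs(np.sin(phase + wf.shank_phase)))
        t_chunks.append(tt)
        spans.append((t0, t0 + n * dt, activity))
        t0 = t0 + n * dt
        if bout_index < len(activity_schedule) - 1:
            t0 = standing(params.bout_gap, t0)
    t0 = standing(1.0, t0)

    t = np.concatenate(t_chunks)
    thigh = np.concatenate(thigh_chunks)
    shank = np.concatenate(shank_chunks)
    if params.noise_sd > 0:
        thigh = thigh + params.noise_sd * rng.standard_normal(len(t))
        shank = shank + params.noise_sd * rng.standard_normal(len(t))

    def channels(incl: np.ndarray) -> SensorChannels:
        gyro = np.zeros((len(t), 3))
        gyro[:, 0] = np.gradient(incl, dt)
        gyro[:, 1:] = 0.1 * rng.standard_normal((len(t), 2))
        accel = np.zeros((len(t), 3))
        accel[:, 0] = np.gradient(gyro[:, 0], dt) * 0.05
        accel[:, 2] = 9.81 + 0.2 * rng.standard_normal(len(t))
        accel[:, 1] = 0.2 * rng.standard_normal(len(t))
        return SensorChannels(inclination=incl, angular_velocity=gyro, acceleration=accel)

    recording = InertialRecording(
        timestamps=t,
        thigh=channels(thigh),
        shank=channels(shank),
        subject_id=subject_id,
        trial_id=trial_id,
    )
    return recording, spans


def spans_to_window_labels(windows, spans: Sequence[Span]) -> List[Optional[ActivityClass]]:
    """Label stride windows by the bout span containing their midpoint (else None)."""
    labels: List[Optional[ActivityClass]] = []
    for window in windows:
        mid = window.midpoint_time
        label = next((cls for (a, b, cls) in spans if a <= mid <= b), None)
        labels.append(label)
    return labels


#: Default per-trial schedule: level walking about twice as frequent as stairs.
DEFAULT_SCHEDULE: Tuple[Tuple[ActivityClass, int], ...] = (
    (ActivityClass.WALK, 24),
    (ActivityClass.STAIRS_UP, 12),
    (ActivityClass.STAIRS_DOWN, 12),
)


def generate_labeled_dataset(
    n_subjects: int = 20,
    trials_per_subject: int = 1,
    schedule: Sequence[Tuple[ActivityClass, int]] = DEFAULT_SCHEDULE,
    params: GaitGeneratorParams = GaitGeneratorParams(),
    detector: StepDetectorConfig = StepDetectorConfig(),
) -> List[LabeledSample]:
    """Run the real pipeline over generated trials and keep ground-truth labels."""
    samples: List[LabeledSample] = []
    for si in range(n_subjects):
        subject_id = f"S{si:02d}"
        for ti in range(trials_per_subject):
            trial_id = f"T{ti}"
            recording, spans = generate_gait_recording(schedule, params, subject_id, trial_id)
            events = detect_step_events(recording, detector)
            windows = segment_steps(events, recording.timestamps, detector)
            labels = spans_to_window_labels(windows, spans)
            for window, label in zip(windows, labels):
                if label is None:
                    continue
                samples.append(
                    LabeledSample(
                        features=extract_features(recording, window),
                        label=label,
                        subject_id=subject_id,
                        trial_id=trial_id,
                    )
                )
    return samples


# ---------------------------------------------------------------------------
# ground-truth networks


def _line(frame: LocalFrame, xy_points) -> np.ndarray:
    return frame.to_lonlat(np.asarray(xy_points, dtype=float))


def generate_truth_network(template: str = "corridor_with_stairs") -> MapStore:
    """Deterministic ground-truth network for one of the known templates.

    * ``corridor_with_stairs`` — a 46 m hallway flanked by two 21-step
      staircases; 3 paths, 2 crossings.
    * ``plus_junction`` — four 60 m walkways meeting at one central crossing.
    * ``campus_grid`` — a 2x2 block grid (3x3 nodes, 50 m spacing): 12 edge
      paths, 9 crossings.
    """
    frame = LocalFrame(BASE_LON, BASE_LAT)
    store = MapStore()
    if template == "corridor_with_stairs":
        stairs_len = 8.0
        hallway_len = 46.0
        x0 = 0.0
        p_stairs1 = PathRecord(
            geometry=_line(frame, [[x0, 0], [x0 + stairs_len, 0]]),
            path_type="stairs_up",
            properties={"stair_count": 21},
        )
        p_hall = PathRecord(
            geometry=_line(frame, [[x0 + stairs_len, 0], [x0 + stairs_len + hallway_len, 0]]),
            path_type="walk",
        )
        p_stairs2 = PathRecord(
            geometry=_line(frame, [[x0 + stairs_len + hallway_len, 0], [x0 + 2 * stairs_len + hallway_len, 0]]),
            path_type="stairs_up",
            properties={"stair_count": 21},
        )
        id1 = store.add_path(p_stairs1)
        idh = store.add_path(p_hall)
        id2 = store.add_path(p_stairs2)
        c1 = store.add_crossing(Crossing(location=tuple(_line(frame, [[x0 + stairs_len, 0]])[0])))
        c2 = store.add_crossing(Crossing(location=tuple(_line(frame, [[x0 + stairs_len + hallway_len, 0]])[0])))
        store.link(id1, "end", c1)
        store.link(idh, "start", c1)
        store.link(idh, "end", c2)
        store.link(id2, "start", c2)
    elif template == "plus_junction":
        arm = 60.0
        center = np.array([0.0, 0.0])
        ids = []
        for dx, dy in ((0, 1), (1, 0), (0, -1), (-1, 0)):
            tip = center + arm * np.array([dx, dy])
            rec = PathRecord(geometry=_line(frame, [center, tip]), path_type="walk")
            ids.append(store.add_path(rec))
        cid = store.add_crossing(Crossing(location=tuple(_line(frame, [center])[0])))
        for pid in ids:
            store.link(pid, "start", cid)
    elif template == "campus_grid":
        spacing = 50.0
        node_ids = {}
        for ix in range(3):
            for iy in range(3):
                loc = tuple(_line(frame, [[ix * spacing, iy * spacing]])[0])
                node_ids[(ix, iy)] = store.add_crossing(Crossing(location=loc))
        for ix in range(3):
            for iy in range(3):
                for jx, jy in ((ix + 1, iy), (ix, iy + 1)):
                    if jx > 2 or jy > 2:
                        continue
                    rec = PathRecord(
                        geometry=_line(frame, [[ix * spacing, iy * spacing], [jx * spacing, jy * spacing]]),
                        path_type="walk",
                    )
                    pid = store.add_path(rec)
                    store.link(pid, "start", node_ids[(ix, iy)])
                    store.link(pid, "end", node_ids[(jx, jy)])
    else:
        raise InvalidInputError(f"unknown template {template!r}")
    store.assert_consistent()
    return store


def _route_geometry(network: MapStore, route: Sequence[str], tol: float = 1.0) -> np.ndarray:
    """Concatenate path geometries of a route, verifying connectivity."""
    if not route:
        raise InvalidInputError("route must name at least one path")
    frame = LocalFrame.for_points(*[network.get_path(pid).geometry for pid in route])
    chain: Optional[np.ndarray] = None
    for pid in route:
        geom = frame.to_xy(network.get_path(pid).geometry)
        if chain is None:
            chain = geom
            continue
        tail = chain[-1]
        d_start = np.linalg.norm(geom[0] - tail)
        d_end = np.linalg.norm(geom[-1] - tail)
        if min(d_start, d_end) > tol:
            # maybe the previous path needed flipping (single-path chains only)
            if len(chain) and np.linalg.norm(chain[0] - geom[0]) <= tol:
                chain = chain[::-1]
                d_start = np.linalg.norm(geom[0] - chain[-1])
                d_end = np.linalg.norm(geom[-1] - chain[-1])
            if min(d_start, d_end) > tol:
                raise InvalidInputError(f"route is not connected at path {pid}")
        nxt = geom if d_start <= d_end else geom[::-1]
        chain = np.vstack([chain, nxt[1:]])
    return frame.to_lonlat(chain)


def generate_gps_trace(
    network: MapStore,
    route: Sequence[str],
    params: TraceGeneratorParams = TraceGeneratorParams(),
    start_time: float = 0.0,
) -> List[GeoFix]:
    """Noisy GPS fixes of a walk along a connected route through the network.

    Fixes are spaced ``walking_speed * fix_interval`` metres apart along the
    route with isotropic Gaussian noise; with ``reflection_probability`` a
    contiguous middle run of fixes is displaced by ``reflection_offset``
    metres in a random direction.
    """
    geometry = _route_geometry(network, route)
    total = polyline_arclength(geometry)[-1]
    rng = np.random.default_rng([params.seed, zlib.crc32("/".join(route).encode())])
    step = max(params.walking_speed * params.fix_interval, 1e-6)
    arcs = np.arange(0.0, total + step / 2, step)
    arcs[-1] = min(arcs[-1], total)
    points = np.array([point_at_arc(geometry, s) for s in arcs])
    frame = LocalFrame.for_points(geometry)
    xy = frame.to_xy(points)
    if params.position_noise_sd > 0:
        xy = xy + params.position_noise_sd * rng.standard_normal(xy.shape)
    if params.reflection_probability > 0 and rng.random() < params.reflection_probability:
        n = len(xy)
        run_len = max(int(0.2 * n), 2)
        start = int(rng.integers(n // 4, max(n // 4 + 1, n - run_len - n // 4)))
        # displace perpendicular to the local route direction, as a facade would
        clean = frame.to_xy(points)
        a = clean[max(start - 1, 0)]
        b = clean[min(start + run_len, n - 1)]
        direction = b - a
        norm = np.linalg.norm(direction)
        direction = direction / norm if norm > 0 else np.array([1.0, 0.0])
        side = 1.0 if rng.random() < 0.5 else -1.0
        normal = side * np.array([-direction[1], direction[0]])
        xy[start : start + run_len] += params.reflection_offset * normal
    lonlat = frame.to_lonlat(xy)
    times = start_time + params.fix_interval * np.arange(len(lonlat))
    return [GeoFix(time=float(t), latitude=float(lat), longitude=float(lon)) for t, (lon, lat) in zip(times, lonlat)]
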