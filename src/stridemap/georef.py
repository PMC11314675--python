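"""Geographic referencing of classified steps.

Smartphone GPS fixes arrive at a lower and less regular rate than strides,
so fix positions are linearly interpolated in time to the timepoint of each
step (anchored at the stride window's start, i.e. the heel strike).  Linear
interpolation is done per coordinate in degrees; over the few metres between
fixes the curvature error is negligible.  GPX 1.1 is the trace input format;
classified steps are exported as a GeoJSON FeatureCollection of points.
"""

from __future__ import annotations

import datetime as _dt
import json
import xml.etree.ElementTree as ET
from dataclasses import dataclass
from typing import List, Optional, Sequence

import numpy as np

from .errors import InvalidInputError, MissingTimeError, OutOfRangeError
from .gait import StepDetectorConfig, detect_and_segment
from .features import extract_feature_matrix
from .har import ActivityClass, TrainedModel
from .recording import InertialRecording

_GPX_NS = "http://www.topografix.com/GPX/1/1"


@dataclass(frozen=True)
class GeoFix:
    """One GPS fix on the same clock as the IMU timestamps."""

    time: float
    latitude: float
    longitude: float
    accuracy: Optional[float] = None

    def __post_init__(self):
        if not -90.0 <= self.latitude <= 90.0:
            raise InvalidInputError(f"latitude {self.latitude} outside [-90, 90]")
        if not -180.0 <= self.longitude <= 180.0:
            raise InvalidInputError(f"longitude {self.longitude} outside [-180, 180]")


@dataclass(frozen=True)
class ClassifiedStep:
    """A stride with its WGS84 position and predicted activity."""

    time: float
    latitude: float
    longitude: float
    activity: ActivityClass


def interpolate_fixes(fixes: Sequence[GeoFix], step_times: Sequence[float]) -> List[tuple]:
    """Linearly interpolate fix coordinates to the given step times.

    Returns (latitude, longitude) pairs.  Step times outside the fix span are
    rejected with an :class:`OutOfRangeError` listing the offending times.
    """
    if len(fixes) < 2:
        raise InvalidInputError("need at least 2 fixes to interpolate")
    times = np.array([f.time for f in fixes], dtype=float)
    if np.any(np.diff(times) < 0):
        raise InvalidInputError("fixes must be time-ordered")
    step_times = np.asarray(step_times, dtype=float)
    outside = step_times[(step_times < times[0]) | (step_times > times[-1])]
    if outside.size:
        raise OutOfRangeError(
            f"step times outside the GPS span [{times[0]}, {times[-1]}]: {outside.tolist()}",
            offending=outside.tolist(),
        )
    lats = np.interp(step_times, times, [f.latitude for f in fixes])
    lons = np.interp(step_times, times, [f.longitude for f in fixes])
    return list(zip(lats.tolist(), lons.tolist()))


# -- GPX 1.1 ----------------------------------------------------------------


def _parse_gpx_time(text: str) -> float:
    text = text.strip()
    if text.endswith("Z"):
        text = text[:-1] + "+00:00"
    dt = _dt.datetime.fromisoformat(text)
    if dt.tzinfo is None:
        dt = dt.replace(tzinfo=_dt.timezone.utc)
    return dt.timestamp()


def read_gpx(source) -> List[List[GeoFix]]:
    """Parse a GPX 1.1 file into one fix list per track.

    Track segments within a track are concatenated in document order.  ISO
    timestamps are converted to POSIX seconds.  Tracks without timestamps
    raise :class:`MissingTimeError`; malformed XML raises ``ET.ParseError``.
    """
    tree = ET.parse(source)
    root = tree.getroot()

    def findall(elem, tag):
        return elem.findall(f"{{{_GPX_NS}}}{tag}") or elem.findall(tag)

    traces: List[List[GeoFix]] = []
    for trk in findall(root, "trk"):
        fixes: List[GeoFix] = []
        for seg in findall(trk, "trkseg"):
            for pt in findall(seg, "trkpt"):
                time_el = findall(pt, "time")
                if not time_el:
                    raise MissingTimeError("trackpoint without a <time> element")
                fixes.append(
                    GeoFix(
                        time=_parse_gpx_time(time_el[0].text),
                        latitude=float(pt.attrib["lat"]),
                        longitude=float(pt.attrib["lon"]),
                    )
                )
        traces.append(fixes)
    return traces


def write_gpx(traces: Sequence[Sequence[GeoFix]], path) -> None:
    """Write fix lists as one GPX 1.1 track each (times as UTC ISO-8601)."""
    root = ET.Element("gpx", attrib={"version": "1.1", "creator": "stridemap", "xmlns": _GPX_NS})
    for fixes in traces:
        trk = ET.SubElement(root, "trk")
        seg = ET.SubElement(trk, "trkseg")
        for fix in fixes:
            pt = ET.SubElement(seg, "trkpt", attrib={"lat": f"{fix.latitude:.8f}", "lon": f"{fix.longitude:.8f}"})
            stamp = _dt.datetime.fromtimestamp(fix.time, tz=_dt.timezone.utc)
            ET.SubElement(pt, "time").text = stamp.isoformat(timespec="microseconds").replace("+00:00", "Z")
    ET.ElementTree(root).write(path, encoding="unicode", xml_declaration=True)


# -- pipeline ---------------------------------------------------------------


def classify_and_georeference(
    recording: InertialRecording,
    fixes: Sequence[GeoFix],
    model: TrainedModel,
    detector: StepDetectorConfig = StepDetectorConfig(),
    clock_offset: float = 0.0,
) -> List[ClassifiedStep]:
    """Full per-trial pipeline: detect, segment, extract, classify, position.

    ``clock_offset`` (seconds, added to IMU times) absorbs a constant shift
    between the IMU and GPS clocks.  Strides whose start time falls outside
    the GPS span are dropped.
    """
    windows = detect_and_segment(recording, detector)
    if not windows:
        return []
    span = (fixes[0].time, fixes[-1].time) if fixes else (0.0, -1.0)
    kept = [w for w in windows if span[0] <= w.start_time + clock_offset <= span[1]]
    if not kept:
        return []
    X = extract_feature_matrix(recording, kept)
    labels = model.predict(X)
    positions = interpolate_fixes(fixes, [w.start_time + clock_offset for w in kept])
    return [
        ClassifiedStep(time=w.start_time, latitude=lat, longitude=lon, activity=label)
        for w, (lat, lon), label in zip(kept, positions, labels)
    ]


#: Rendering hint: level walking red, stair activities green.
_STYLE = {
    ActivityClass.WALK: "red",
    ActivityClass.STAIRS_UP: "green",
    ActivityClass.STAIRS_DOWN: "green",
}


def steps_to_geojson(steps: Sequence[ClassifiedStep], path=None) -> dict:
    """Classified steps as a GeoJSON FeatureCollection of points."""
    features = [
        {
            "type": "Feature",
            "geometry": {"type": "Point", "coordinates": [s.longitude, s.latitude]},
            "properties": {"time": s.time, "activity": s.activity.value, "marker-color": _STYLE[s.activity]},
        }
        for s in steps
    ]
    collection = {"type": "FeatureCollection", "features": features}
    if path is not None:
        with open(path, "w") as fh:
            json.dump(collection, fh, indent=2)
    return collection
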