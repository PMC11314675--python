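"""Map-layer data model: typed path polylines joined by crossings.

Paths and crossings form a bidirectional graph: paths are edges, crossings
are nodes.  Each path is an ordered sequence of WGS84 points with a type
derived from the movement activity (or the generic ``trail``), a property
map (stairs carry a ``stair_count``), and a merge count recording how many
traces the path aggregates — the weight used when paths are averaged.

Crossing locations are stored explicitly and are authoritative; every
connection is kept referentially symmetric (a crossing lists (path, end)
pairs and the path's corresponding crossing field points back).  The
:class:`MapStore` keeps the whole network in memory behind a small storage
contract (insert / delete / update / get / bounding-box query) and persists
to a GeoJSON FeatureCollection, which also renders directly in GIS tools.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Set, Tuple

import numpy as np
from shapely.geometry import LineString

from .errors import ConsistencyError, InvalidInputError
from .geo import EARTH_RADIUS_M, LocalFrame, polyline_arclength

PATH_TYPES = ("trail", "walk", "stairs_up", "stairs_down")
STAIR_TYPES = frozenset({"stairs_up", "stairs_down"})

#: (path_id, end) reference; end is "start" or "end".
EndRef = Tuple[str, str]


@dataclass
class PathRecord:
    """A typed geographic polyline with properties and a merge count."""

    geometry: np.ndarray  # (N,2) lon/lat degrees
    path_type: str = "trail"
    properties: Dict = field(default_factory=dict)
    merge_count: int = 1
    id: Optional[str] = None
    start_crossing: Optional[str] = None
    end_crossing: Optional[str] = None

    def __post_init__(self):
        self.geometry = np.asarray(self.geometry, dtype=float).reshape(-1, 2)
        self.validate()

    def validate(self) -> None:
        if self.geometry.shape[0] < 2:
            raise InvalidInputError("a path needs at least 2 points")
        if self.path_type not in PATH_TYPES:
            raise InvalidInputError(f"path_type must be one of {PATH_TYPES}")
        if self.merge_count < 1:
            raise InvalidInputError("merge_count must be >= 1")
        has_stairs = "stair_count" in self.properties
        if self.path_type in STAIR_TYPES and not has_stairs:
            raise InvalidInputError("stairs paths must carry a stair_count property")
        if self.path_type not in STAIR_TYPES and has_stairs:
            raise InvalidInputError("stair_count is only valid on stairs paths")
        if has_stairs and int(self.properties["stair_count"]) < 0:
            raise InvalidInputError("stair_count must be non-negative")

    def crossing_at(self, end: str) -> Optional[str]:
        return self.start_crossing if end == "start" else self.end_crossing

    def endpoint(self, end: str) -> np.ndarray:
        return self.geometry[0] if end == "start" else self.geometry[-1]


@dataclass
class Crossing:
    """Graph node joining path ends at an explicit WGS84 location."""

    location: Tuple[float, float]  # (lon, lat)
    id: Optional[str] = None
    connections: Set[EndRef] = field(default_factory=set)


def path_length(path: PathRecord) -> float:
    """Geodesic length of the polyline in metres."""
    return float(polyline_arclength(path.geometry)[-1])


def path_centroid(path: PathRecord) -> Tuple[float, float]:
    """Arc-length-weighted centroid of the polyline, as (lon, lat)."""
    frame = LocalFrame.for_points(path.geometry)
    line = LineString(frame.to_xy(path.geometry))
    if line.length == 0:
        lon, lat = path.geometry.mean(axis=0)
        return float(lon), float(lat)
    lon, lat = frame.to_lonlat(np.array(line.centroid.coords[0]))
    return float(lon), float(lat)


def path_bbox(path: PathRecord) -> Tuple[float, float, float, float]:
    """Tight vertex bounding box as (min_lon, min_lat, max_lon, max_lat)."""
    g = path.geometry
    return (float(g[:, 0].min()), float(g[:, 1].min()), float(g[:, 0].max()), float(g[:, 1].max()))


def _bbox_intersects(a, b) -> bool:
    return not (a[2] < b[0] or b[2] < a[0] or a[3] < b[1] or b[3] < a[1])


class MapStore:
    """In-memory path/crossing store with GeoJSON persistence.

    Mutations that touch crossing links go through :meth:`link` / ``unlink``
    so referential symmetry is maintained; :meth:`audit` verifies it along
    with the no-orphan-crossing and no-zero-length-path invariants.
    """

    def __init__(self):
        self.paths: Dict[str, PathRecord] = {}
        self.crossings: Dict[str, Crossing] = {}
        self._next_path = 1
        self._next_crossing = 1

    # -- path CRUD ----------------------------------------------------------

    def add_path(self, record: PathRecord) -> str:
        record.validate()
        if record.id is None:
            record.id = f"p{self._next_path}"
            self._next_path += 1
        elif record.id in self.paths:
            raise ConsistencyError(f"duplicate path id {record.id}")
        else:
            # keep the counter ahead of externally supplied numeric ids
            try:
                self._next_path = max(self._next_path, int(record.id.lstrip("p")) + 1)
            except ValueError:
                pass
        record.start_crossing = None
        record.end_crossing = None
        self.paths[record.id] = record
        return record.id

    def get_path(self, path_id: str) -> PathRecord:
        if path_id not in self.paths:
            raise ConsistencyError(f"unknown path {path_id}")
        return self.paths[path_id]

    def update_path(self, record: PathRecord) -> None:
        if record.id not in self.paths:
            raise ConsistencyError(f"unknown path {record.id}")
        record.validate()
        self.paths[record.id] = record

    def delete_path(self, path_id: str) -> None:
        record = self.get_path(path_id)
        for end in ("start", "end"):
            if record.crossing_at(end) is not None:
                self.unlink(path_id, end)
        del self.paths[path_id]

    def query_bbox(self, bbox: Tuple[float, float, float, float]) -> List[PathRecord]:
        """All paths whose vertex bbox intersects the query bbox (superset guarantee)."""
        return [p for p in self.paths.values() if _bbox_intersects(path_bbox(p), bbox)]

    # -- crossing CRUD ------------------------------------------------------

    def add_crossing(self, crossing: Crossing) -> str:
        if crossing.id is None:
            crossing.id = f"c{self._next_crossing}"
            self._next_crossing += 1
        elif crossing.id in self.crossings:
            raise ConsistencyError(f"duplicate crossing id {crossing.id}")
        else:
            try:
                self._next_crossing = max(self._next_crossing, int(crossing.id.lstrip("c")) + 1)
            except ValueError:
                pass
        self.crossings[crossing.id] = crossing
        return crossing.id

    def get_crossing(self, crossing_id: str) -> Crossing:
        if crossing_id not in self.crossings:
            raise ConsistencyError(f"unknown crossing {crossing_id}")
        return self.crossings[crossing_id]

    def link(self, path_id: str, end: str, crossing_id: str) -> None:
        """Attach a path end to a crossing, keeping both sides in sync."""
        record = self.get_path(path_id)
        crossing = self.get_crossing(crossing_id)
        current = record.crossing_at(end)
        if current == crossing_id:
            return
        if current is not None:
            self.unlink(path_id, end)
        crossing.connections.add((path_id, end))
        if end == "start":
            record.start_crossing = crossing_id
        else:
            record.end_crossing = crossing_id

    def unlink(self, path_id: str, end: str) -> None:
        record = self.get_path(path_id)
        crossing_id = record.crossing_at(end)
        if crossing_id is None:
            return
        crossing = self.get_crossing(crossing_id)
        crossing.connections.discard((path_id, end))
        if end == "start":
            record.start_crossing = None
        else:
            record.end_crossing = None
        if not crossing.connections:
            del self.crossings[crossing_id]

    # -- consistency --------------------------------------------------------

    def audit(self) -> List[str]:
        """Return a list of consistency violations (empty means consistent)."""
        issues: List[str] = []
        for cid, crossing in self.crossings.items():
            if not crossing.connections:
                issues.append(f"orphan crossing {cid}")
            for path_id, end in crossing.connections:
                if path_id not in self.paths:
                    issues.append(f"crossing {cid} references missing path {path_id}")
                elif self.paths[path_id].crossing_at(end) != cid:
                    issues.append(f"asymmetric link {cid} <-> {path_id}.{end}")
        for pid, record in self.paths.items():
            for end in ("start", "end"):
                cid = record.crossing_at(end)
                if cid is None:
                    continue
                if cid not in self.crossings:
                    issues.append(f"path {pid}.{end} references missing crossing {cid}")
                elif (pid, end) not in self.crossings[cid].connections:
                    issues.append(f"asymmetric link {pid}.{end} -> {cid}")
            if path_length(record) <= 1e-6:
                issues.append(f"zero-length path {pid}")
        return issues

    def assert_consistent(self) -> None:
        issues = self.audit()
        if issues:
            raise ConsistencyError("; ".join(issues))

    # -- snapshots ----------------------------------------------------------

    def copy(self) -> "MapStore":
        return copy.deepcopy(self)

    def restore(self, other: "MapStore") -> None:
        self.paths = other.paths
        self.crossings = other.crossings
        self._next_path = other._next_path
        self._next_crossing = other._next_crossing

    # -- GeoJSON persistence ------------------------------------------------

    def to_geojson(self) -> dict:
        features = []
        for record in self.paths.values():
            props = {
                "kind": "path",
                "id": record.id,
                "path_type": record.path_type,
                "merge_count": record.merge_count,
                "start_crossing": record.start_crossing,
                "end_crossing": record.end_crossing,
            }
            props.update(record.properties)
            features.append(
                {
                    "type": "Feature",
                    "geometry": {"type": "LineString", "coordinates": [[float(x), float(y)] for x, y in record.geometry]},
                    "properties": props,
                }
            )
        for crossing in self.crossings.values():
            features.append(
                {
                    "type": "Feature",
                    "geometry": {"type": "Point", "coordinates": [float(crossing.location[0]), float(crossing.location[1])]},
                    "properties": {
                        "kind": "crossing",
                        "id": crossing.id,
                        "connections": sorted([pid, end] for pid, end in crossing.connections),
                    },
                }
            )
        return {"type": "FeatureCollection", "features": features}

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_geojson(), fh, indent=2)

    @classmethod
    def from_geojson(cls, collection: dict) -> "MapStore":
        store = cls()
        crossing_features = []
        for feature in collection.get("features", []):
            props = dict(feature.get("properties") or {})
            kind = props.pop("kind", None)
            if kind == "path" or feature["geometry"]["type"] == "LineString":
                path_type = props.pop("path_type", "trail")
                merge_count = int(props.pop("merge_count", 1))
                path_id = props.pop("id", None)
                props.pop("start_crossing", None)
                props.pop("end_crossing", None)
                store.add_path(
                    PathRecord(
                        geometry=np.array(feature["geometry"]["coordinates"], dtype=float),
                        path_type=path_type,
                        properties=props,
                        merge_count=merge_count,
                        id=path_id,
                    )
                )
            else:
                crossing_features.append((feature, props))
        for feature, props in crossing_features:
            lon, lat = feature["geometry"]["coordinates"]
            cid = store.add_crossing(Crossing(location=(lon, lat), id=props.get("id")))
            for path_id, end in props.get("connections", []):
                store.link(path_id, end, cid)
        store.assert_consistent()
        return store

    @classmethod
    def load(cls, path) -> "MapStore":
        with open(path) as fh:
            return cls.from_geojson(json.load(fh))


def query_candidates(store: MapStore, path: PathRecord, pad_m: float = 0.0) -> List[PathRecord]:
    """Stored paths whose bounding box intersects the new path's bounding box.

    ``pad_m`` expands the query box by a metre margin on every side; matching
    passes its match distance here so thin paths running parallel to the new
    one are not missed by the degenerate boxes of straight polylines.
    """
    min_lon, min_lat, max_lon, max_lat = path_bbox(path)
    if pad_m > 0.0:
        dlat = pad_m / (EARTH_RADIUS_M * np.pi / 180.0)
        dlon = dlat / max(np.cos(np.radians(0.5 * (min_lat + max_lat))), 1e-9)
        min_lon, min_lat, max_lon, max_lat = min_lon - dlon, min_lat - dlat, max_lon + dlon, max_lat + dlat
    return store.query_bbox((min_lon, min_lat, max_lon, max_lat))
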