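"""Iterative map construction from georeferenced, activity-typed traces.

A new trace enters the map in four stages: it is simplified into
non-self-intersecting segments; candidate paths are fetched by bounding box;
each segment is partitioned into stretches that match a candidate (within a
lateral distance and a heading tolerance, headings compared modulo 180
degrees because paths are bidirectional) and stretches that match nothing;
matching stretches are merged into their candidate with a merge-count
weighted average, non-matching stretches become new paths, and connectors
(crossings) are inserted wherever matching and non-matching parts meet.
Merging raises a path's merge count, so a path's weight — and its stability
against a single noisy trace — grows with every trace it absorbs.  Paths
that never merge can later be pruned as suspected measurement artefacts
(e.g. GPS multipath reflections).

The matching thresholds are deliberate engineering choices collected in
:class:`BuilderConfig`; distance-plus-heading is the minimal criterion that
keeps a trace crossing a path perpendicularly from "matching" it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import shapely
from shapely.geometry import LineString
from shapely.ops import unary_union

from .errors import ConsistencyError, InvalidInputError, PathTypeMismatchError
from .geo import LocalFrame, haversine_m, point_at_arc, polyline_arclength
from .georef import ClassifiedStep, GeoFix
from .har import ActivityClass
from .pathmodel import (
    Crossing,
    EndRef,
    MapStore,
    PathRecord,
    STAIR_TYPES,
    path_length,
    query_candidates,
)


@dataclass(frozen=True)
class BuilderConfig:
    """Tolerances of the insertion algorithm (all metres/degrees, > 0)."""

    match_distance: float = 5.0  # m: max lateral offset for a point to match a path
    match_angle: float = 45.0  # deg: max heading difference (mod 180)
    resample_spacing: float = 1.0  # m: sampling step for matching and averaging
    crossing_snap: float = 2.0  # m: connectors closer than this are one crossing
    simplify_tolerance: float = 0.5  # m: max deviation allowed when downsampling
    min_match_length: float = 3.0  # m: shorter matching runs are demoted
    heading_window: float = 2.0  # m: chord length over which headings are estimated
    trace_smooth_window: int = 5  # fixes: moving-average window for raw GPS traces
    respect_path_types: bool = True  # False reproduces the untyped "all trails" mode

    def __post_init__(self):
        for name in ("match_distance", "match_angle", "resample_spacing", "crossing_snap", "simplify_tolerance", "min_match_length", "heading_window"):
            if getattr(self, name) <= 0:
                raise InvalidInputError(f"BuilderConfig.{name} must be strictly positive")


@dataclass
class MatchResult:
    """Partition of a new path into matched and unmatched arc-length ranges.

    ``matched`` pairs a range on the new path with the corresponding range on
    the candidate (the candidate range is reversed when the paths are
    anti-parallel); ``unmatched`` ranges complete the partition.
    """

    matched: List[Tuple[Tuple[float, float], Tuple[float, float]]] = field(default_factory=list)
    unmatched: List[Tuple[float, float]] = field(default_factory=list)


@dataclass
class InsertionReport:
    """What one insert_path call did to the store."""

    created: List[str] = field(default_factory=list)
    merged: List[str] = field(default_factory=list)
    deleted: List[str] = field(default_factory=list)
    crossings: List[str] = field(default_factory=list)

    def to_dict(self) -> Dict:
        return {"created": self.created, "merged": self.merged, "deleted": self.deleted, "crossings": self.crossings}


# ---------------------------------------------------------------------------
# property bookkeeping


def _apportion(total: int, fracs: Sequence[float]) -> List[int]:
    """Integers proportional to fracs that sum exactly to total (largest remainder)."""
    raw = np.asarray(fracs, dtype=float) * total
    base = np.floor(raw).astype(int)
    short = total - int(base.sum())
    order = np.argsort(-(raw - base))
    for i in range(short):
        base[order[i]] += 1
    return base.tolist()


def _divide_props(props: Dict, fracs: Sequence[float]) -> List[Dict]:
    """Redistribute numeric properties over parts, proportionally to arc length."""
    parts: List[Dict] = [dict() for _ in fracs]
    for key, value in props.items():
        if key == "stair_count":
            for part, count in zip(parts, _apportion(int(value), fracs)):
                part[key] = count
        elif isinstance(value, (int, float)) and not isinstance(value, bool):
            for part, frac in zip(parts, fracs):
                part[key] = value * frac
        else:
            for part in parts:
                part[key] = value
    return parts


def _sub_geometry(geometry: np.ndarray, a: float, b: float) -> np.ndarray:
    """Vertices of the polyline between arc lengths a and b (metres), inclusive."""
    cum = polyline_arclength(geometry)
    a = float(np.clip(a, 0.0, cum[-1]))
    b = float(np.clip(b, 0.0, cum[-1]))
    if b <= a:
        raise InvalidInputError("empty sub-geometry")
    inner = geometry[(cum > a + 1e-9) & (cum < b - 1e-9)]
    pts = np.vstack([point_at_arc(geometry, a), inner, point_at_arc(geometry, b)])
    keep = np.concatenate([[True], np.linalg.norm(np.diff(pts, axis=0), axis=1) > 1e-12])
    pts = pts[keep]
    if pts.shape[0] < 2:
        pts = np.vstack([point_at_arc(geometry, a), point_at_arc(geometry, b)])
    return pts


# ---------------------------------------------------------------------------
# simplification


def _split_loops(xy: np.ndarray) -> List[np.ndarray]:
    """Cut a polyline (metric frame) at self-intersections into simple pieces."""
    # drop duplicate consecutive vertices first
    keep = np.concatenate([[True], np.linalg.norm(np.diff(xy, axis=0), axis=1) > 1e-9])
    xy = xy[keep]
    pieces: List[np.ndarray] = []
    cur: List[np.ndarray] = [xy[0]]
    i = 1
    while i < len(xy):
        p = xy[i]
        hit = _first_intersection(np.asarray(cur), p)
        if hit is None:
            cur.append(p)
            i += 1
        else:
            x = hit
            if np.linalg.norm(x - cur[-1]) > 1e-9:
                cur.append(x)
            pieces.append(np.asarray(cur))
            cur = [x, p] if np.linalg.norm(p - x) > 1e-9 else [x]
            i += 1
    if len(cur) >= 2:
        pieces.append(np.asarray(cur))
    return [p for p in pieces if len(p) >= 2]


def _first_intersection(cur: np.ndarray, p: np.ndarray) -> Optional[np.ndarray]:
    """Earliest crossing of segment cur[-1]->p with the non-adjacent part of cur."""
    if len(cur) < 3:
        return None
    a1 = cur[:-2]
    a2 = cur[1:-1]
    b1, b2 = cur[-1], p
    r = a2 - a1
    q = b2 - b1
    denom = r[:, 0] * q[1] - r[:, 1] * q[0]
    with np.errstate(divide="ignore", invalid="ignore"):
        diff = b1 - a1
        t = (diff[:, 0] * q[1] - diff[:, 1] * q[0]) / denom
        u = (diff[:, 0] * r[:, 1] - diff[:, 1] * r[:, 0]) / denom
    ok = np.isfinite(t) & np.isfinite(u) & (t >= -1e-12) & (t <= 1 + 1e-12) & (u >= -1e-12) & (u <= 1 + 1e-12)
    if not np.any(ok):
        return None
    u_ok = np.where(ok, u, np.inf)
    j = int(np.argmin(u_ok))
    return b1 + u[j] * q


def simplify_path(path: PathRecord, config: BuilderConfig = BuilderConfig()) -> List[PathRecord]:
    """Split at self-intersections and downsample each piece (Douglas-Peucker).

    Endpoints of every piece are preserved and no removed vertex deviates by
    more than ``simplify_tolerance`` from the output polyline; the
    concatenated pieces cover the input.
    """
    frame = LocalFrame.for_points(path.geometry)
    xy = frame.to_xy(path.geometry)
    pieces_xy = _split_loops(xy)
    out_geoms: List[np.ndarray] = []
    lengths: List[float] = []
    for piece in pieces_xy:
        line = LineString(piece).simplify(config.simplify_tolerance, preserve_topology=False)
        coords = np.asarray(line.coords)
        if coords.shape[0] < 2 or line.length <= 1e-9:
            continue
        out_geoms.append(frame.to_lonlat(coords))
        lengths.append(line.length)
    total = sum(lengths)
    fracs = [l / total for l in lengths] if total > 0 else []
    prop_parts = _divide_props(path.properties, fracs)
    return [
        PathRecord(geometry=g, path_type=path.path_type, properties=props, merge_count=path.merge_count)
        for g, props in zip(out_geoms, prop_parts)
    ]


# ---------------------------------------------------------------------------
# matching


def _sample_arcs(length: float, spacing: float) -> np.ndarray:
    n = max(int(np.ceil(length / spacing)), 1)
    return np.linspace(0.0, length, n + 1)


def _headings_at(line: LineString, arcs: np.ndarray, window: float) -> np.ndarray:
    """Heading (degrees) of the chord spanning +-window/2 around each arc position."""
    length = line.length
    lo = np.clip(arcs - window / 2.0, 0.0, length)
    hi = np.clip(arcs + window / 2.0, 0.0, length)
    p1 = shapely.line_interpolate_point(line, lo)
    p2 = shapely.line_interpolate_point(line, hi)
    x1, y1 = shapely.get_x(p1), shapely.get_y(p1)
    x2, y2 = shapely.get_x(p2), shapely.get_y(p2)
    return np.degrees(np.arctan2(y2 - y1, x2 - x1))


def _heading_diff(h1: np.ndarray, h2: np.ndarray) -> np.ndarray:
    """Undirected heading difference in [0, 90] degrees (paths are bidirectional)."""
    d = np.abs(h1 - h2) % 180.0
    return np.minimum(d, 180.0 - d)


@dataclass
class _Run:
    s0: float
    s1: float
    cand: Optional[int]  # index into the candidate list, None = unmatched


def _label_runs(arcs: np.ndarray, labels: np.ndarray, config: BuilderConfig) -> List[_Run]:
    """Group equal consecutive sample labels into arc-interval runs."""
    runs: List[_Run] = []
    start = 0
    for i in range(1, len(labels) + 1):
        if i == len(labels) or labels[i] != labels[start]:
            left = 0.0 if start == 0 else 0.5 * (arcs[start - 1] + arcs[start])
            right = arcs[-1] if i == len(labels) else 0.5 * (arcs[i - 1] + arcs[i])
            cand = None if labels[start] < 0 else int(labels[start])
            runs.append(_Run(left, right, cand))
            start = i
    # demote matched runs shorter than the minimum match length
    full = arcs[-1]
    for run in runs:
        if run.cand is not None and (run.s1 - run.s0) < min(config.min_match_length, full):
            run.cand = None
    # coalesce neighbouring runs with equal labels, then absorb slivers
    runs = _coalesce(runs)
    min_piece = config.resample_spacing
    while len(runs) > 1:
        short = next((i for i, r in enumerate(runs) if (r.s1 - r.s0) < min_piece), None)
        if short is None:
            break
        victim = runs.pop(short)
        target = runs[short - 1] if short > 0 else runs[0]
        if short > 0:
            target.s1 = victim.s1
        else:
            target.s0 = victim.s0
        runs = _coalesce(runs)
    return runs


def _coalesce(runs: List[_Run]) -> List[_Run]:
    out: List[_Run] = []
    for run in runs:
        if out and out[-1].cand == run.cand:
            out[-1].s1 = run.s1
        else:
            out.append(_Run(run.s0, run.s1, run.cand))
    return out


def _distance_to_candidate(samples_xy: np.ndarray, headings: np.ndarray, cand_xy: np.ndarray, config: BuilderConfig) -> np.ndarray:
    """Matching distance of each sample to a candidate polyline (inf = no match).

    A sample matches through a specific candidate segment: its perpendicular
    projection must fall within the segment (give or take half a sampling
    step), the offset must be within ``match_distance`` and the headings must
    agree within ``match_angle`` (mod 180).  Projecting within the segment —
    rather than snapping to the nearest vertex — keeps a stretch that merely
    comes close to a path's endpoint from "matching" around the corner.
    """
    a = cand_xy[:-1]
    d = cand_xy[1:] - a
    seg_len = np.linalg.norm(d, axis=1)
    valid = seg_len > 1e-9
    a, d, seg_len = a[valid], d[valid], seg_len[valid]
    if len(a) == 0:
        return np.full(len(samples_xy), np.inf)
    seg_head = np.degrees(np.arctan2(d[:, 1], d[:, 0]))
    rel = samples_xy[:, None, :] - a[None, :, :]
    t = (rel * d[None, :, :]).sum(axis=-1) / seg_len**2
    margin = 0.5 * config.resample_spacing / seg_len
    inside = (t >= -margin) & (t <= 1.0 + margin)
    tc = np.clip(t, 0.0, 1.0)
    proj = a[None, :, :] + tc[..., None] * d[None, :, :]
    dist = np.linalg.norm(samples_xy[:, None, :] - proj, axis=-1)
    ok = (
        inside
        & (dist <= config.match_distance)
        & (_heading_diff(headings[:, None], seg_head[None, :]) <= config.match_angle)
    )
    return np.where(ok, dist, np.inf).min(axis=1)


def _match_labels(
    seg_geometry: np.ndarray,
    candidates: Sequence[PathRecord],
    config: BuilderConfig,
    frame: LocalFrame,
):
    """Per-sample best matching candidate along a segment.

    Returns (segment line in the metric frame, sample arcs, labels, candidate lines).
    """
    xy = frame.to_xy(seg_geometry)
    line = LineString(xy)
    arcs = _sample_arcs(line.length, config.resample_spacing)
    pts = shapely.line_interpolate_point(line, arcs)
    samples_xy = np.column_stack([shapely.get_x(pts), shapely.get_y(pts)])
    head = _headings_at(line, arcs, config.heading_window)
    labels = np.full(len(arcs), -1, dtype=int)
    best_d = np.full(len(arcs), np.inf)
    cand_lines = []
    for k, cand in enumerate(candidates):
        cand_xy = frame.to_xy(cand.geometry)
        cand_lines.append(LineString(cand_xy))
        dist = _distance_to_candidate(samples_xy, head, cand_xy, config)
        upd = dist < best_d
        labels[upd] = k
        best_d[upd] = dist[upd]
    labels[~np.isfinite(best_d)] = -1
    return line, arcs, labels, cand_lines


def match_paths(new_path: PathRecord, candidate: PathRecord, config: BuilderConfig = BuilderConfig()) -> MatchResult:
    """Find where ``new_path`` starts and stops matching ``candidate``.

    A point of the new path matches when it lies within ``match_distance`` of
    the candidate and the local headings differ by at most ``match_angle``
    (mod 180); matching runs shorter than ``min_match_length`` are demoted.
    """
    frame = LocalFrame.for_points(new_path.geometry, candidate.geometry)
    line, arcs, labels, cand_lines = _match_labels(new_path.geometry, [candidate], config, frame)
    runs = _label_runs(arcs, labels, config)
    geo_scale = path_length(new_path) / line.length if line.length > 0 else 1.0
    cline = cand_lines[0]
    cand_scale = path_length(candidate) / cline.length if cline.length > 0 else 1.0
    result = MatchResult()
    for run in runs:
        s_range = (run.s0 * geo_scale, run.s1 * geo_scale)
        if run.cand is None:
            result.unmatched.append(s_range)
        else:
            p0 = shapely.line_interpolate_point(line, run.s0)
            p1 = shapely.line_interpolate_point(line, run.s1)
            c0 = float(shapely.line_locate_point(cline, p0)) * cand_scale
            c1 = float(shapely.line_locate_point(cline, p1)) * cand_scale
            result.matched.append((s_range, (c0, c1)))
    return result


# ---------------------------------------------------------------------------
# split / merge


def split_path(path: PathRecord, arc_position: float) -> Tuple[PathRecord, PathRecord]:
    """Split a path at an arc-length position (metres), between vertices.

    Numeric properties are redistributed proportionally to arc length
    (``stair_count`` as integers that sum to the original); the merge count is
    copied to both parts.  The parts keep the original's outer crossing ids in
    their fields; re-linking them in a store is the caller's job.
    """
    total = path_length(path)
    if not 0.0 < arc_position < total:
        raise InvalidInputError(f"arc_position must be inside (0, {total}), got {arc_position}")
    geom_a = _sub_geometry(path.geometry, 0.0, arc_position)
    geom_b = _sub_geometry(path.geometry, arc_position, total)
    frac = arc_position / total
    props_a, props_b = _divide_props(path.properties, [frac, 1.0 - frac])
    part_a = PathRecord(geometry=geom_a, path_type=path.path_type, properties=props_a, merge_count=path.merge_count)
    part_b = PathRecord(geometry=geom_b, path_type=path.path_type, properties=props_b, merge_count=path.merge_count)
    part_a.start_crossing = path.start_crossing
    part_b.end_crossing = path.end_crossing
    return part_a, part_b


def merge_paths(
    path_a: PathRecord,
    path_b: PathRecord,
    matched_interval: Optional[Tuple[Tuple[float, float], Tuple[float, float]]] = None,
    config: BuilderConfig = BuilderConfig(),
) -> PathRecord:
    """Merge two matching stretches into one merge-count-weighted average path.

    Both stretches are resampled at ``resample_spacing``, paired by arc-length
    fraction (the second stretch is re-oriented if anti-parallel) and averaged
    vertex-wise with weights equal to the merge counts; numeric properties are
    averaged with the same weights and the merge counts add up.  Paths of
    different types refuse to merge unless ``respect_path_types`` is off.
    """
    type_a, type_b = path_a.path_type, path_b.path_type
    if type_a != type_b and config.respect_path_types:
        raise PathTypeMismatchError(f"cannot merge {type_a} with {type_b}")
    wa, wb = float(path_a.merge_count), float(path_b.merge_count)
    if matched_interval is None:
        matched_interval = ((0.0, path_length(path_a)), (0.0, path_length(path_b)))
    (a0, a1), (b0, b1) = matched_interval
    geom_a = _sub_geometry(path_a.geometry, min(a0, a1), max(a0, a1))
    geom_b = _sub_geometry(path_b.geometry, min(b0, b1), max(b0, b1))
    if a0 > a1:
        geom_a = geom_a[::-1]
    if b0 > b1:
        geom_b = geom_b[::-1]
    frame = LocalFrame.for_points(geom_a, geom_b)
    la = LineString(frame.to_xy(geom_a))
    lb = LineString(frame.to_xy(geom_b))
    # re-orient the second stretch if the endpoints pair crosswise
    a_start, a_end = np.asarray(la.coords[0]), np.asarray(la.coords[-1])
    b_start, b_end = np.asarray(lb.coords[0]), np.asarray(lb.coords[-1])
    straight = np.linalg.norm(a_start - b_start) + np.linalg.norm(a_end - b_end)
    crossed = np.linalg.norm(a_start - b_end) + np.linalg.norm(a_end - b_start)
    if crossed < straight:
        lb = LineString(list(lb.coords)[::-1])
    n = max(int(np.ceil(max(la.length, lb.length) / config.resample_spacing)), 1) + 1
    fracs = np.linspace(0.0, 1.0, n)
    pa = shapely.line_interpolate_point(la, fracs * la.length)
    pb = shapely.line_interpolate_point(lb, fracs * lb.length)
    ax, ay = shapely.get_x(pa), shapely.get_y(pa)
    bx, by = shapely.get_x(pb), shapely.get_y(pb)
    merged_xy = np.column_stack([(wa * ax + wb * bx) / (wa + wb), (wa * ay + wb * by) / (wa + wb)])
    merged_type = type_a if wa >= wb else type_b
    props: Dict = {}
    heavier = path_a if wa >= wb else path_b
    for key in set(path_a.properties) | set(path_b.properties):
        va, vb = path_a.properties.get(key), path_b.properties.get(key)
        if isinstance(va, (int, float)) and isinstance(vb, (int, float)) and not isinstance(va, bool):
            value = (wa * va + wb * vb) / (wa + wb)
            props[key] = int(round(value)) if key == "stair_count" else value
        else:
            props[key] = heavier.properties.get(key, va if va is not None else vb)
    if merged_type in STAIR_TYPES and "stair_count" not in props:
        props["stair_count"] = 0
    if merged_type not in STAIR_TYPES:
        props.pop("stair_count", None)
    return PathRecord(
        geometry=frame.to_lonlat(merged_xy),
        path_type=merged_type,
        properties=props,
        merge_count=path_a.merge_count + path_b.merge_count,
    )


# ---------------------------------------------------------------------------
# connectors


def insert_connector(
    store: MapStore,
    boundary_point: Tuple[float, float],
    path_end_refs: Sequence[EndRef],
    config: BuilderConfig = BuilderConfig(),
) -> Crossing:
    """Register path ends at a crossing near a boundary point.

    A crossing within ``crossing_snap`` metres of the point is reused,
    otherwise a new one is created at the point.  Ends that are already
    linked elsewhere keep their link.
    """
    lon, lat = float(boundary_point[0]), float(boundary_point[1])
    for path_id, end in path_end_refs:
        if path_id not in store.paths:
            raise ConsistencyError(f"dangling path reference {path_id}")
    best, best_d = None, np.inf
    for crossing in store.crossings.values():
        d = float(haversine_m(lon, lat, crossing.location[0], crossing.location[1]))
        if d <= config.crossing_snap and d < best_d:
            best, best_d = crossing, d
    to_link = [(pid, end) for pid, end in path_end_refs if store.get_path(pid).crossing_at(end) is None]
    if best is None:
        if not to_link:
            # every end already holds a link; reuse one of those crossings
            # instead of leaving a node with no connections behind
            for pid, end in path_end_refs:
                cid = store.get_path(pid).crossing_at(end)
                if cid is not None:
                    return store.get_crossing(cid)
        cid = store.add_crossing(Crossing(location=(lon, lat)))
        best = store.get_crossing(cid)
    for path_id, end in to_link:
        store.link(path_id, end, best.id)
    return best


# ---------------------------------------------------------------------------
# insertion


def insert_path(store: MapStore, path: PathRecord, config: BuilderConfig = BuilderConfig()) -> InsertionReport:
    """Insert one path into the map (simplify, match, split, merge, connect).

    The insertion is atomic: any failure leaves the store unchanged.
    """
    snapshot = store.copy()
    try:
        report = InsertionReport()
        for segment in simplify_path(path, config):
            if path_length(segment) <= max(1e-6, 0.1 * config.resample_spacing):
                continue
            _insert_segment(store, segment, config, report)
        store.assert_consistent()
        return report
    except Exception:
        store.restore(snapshot)
        raise


def _insert_segment(
    store: MapStore,
    segment: PathRecord,
    config: BuilderConfig,
    report: InsertionReport,
) -> Optional[Tuple[EndRef, EndRef]]:
    frame = LocalFrame.for_points(segment.geometry)
    candidates = [c for c in query_candidates(store, segment, pad_m=config.match_distance)]
    line, arcs, labels, _ = _match_labels(segment.geometry, candidates, config, frame)
    if config.respect_path_types:
        # paths of a different type never match
        for k, cand in enumerate(candidates):
            if cand.path_type != segment.path_type:
                labels[labels == k] = -1
    runs = _label_runs(arcs, labels, config)
    geo_len = path_length(segment)
    scale = geo_len / line.length if line.length > 0 else 1.0
    fracs = [max((r.s1 - r.s0) * scale, 0.0) / geo_len for r in runs]
    prop_parts = _divide_props(segment.properties, fracs)

    placed: List[Tuple[EndRef, EndRef]] = []
    for run, props in zip(runs, prop_parts):
        s0, s1 = run.s0 * scale, run.s1 * scale
        sub_rec = PathRecord(
            geometry=_sub_geometry(segment.geometry, s0, s1),
            path_type=segment.path_type,
            properties=props,
            merge_count=1,
        )
        cand = candidates[run.cand] if run.cand is not None else None
        if cand is None or cand.id not in store.paths:
            if cand is None:
                pid = store.add_path(sub_rec)
                report.created.append(pid)
                placed.append(((pid, "start"), (pid, "end")))
            else:
                # candidate was consumed by an earlier run; re-resolve freshly
                refs = _insert_segment(store, sub_rec, config, report)
                if refs is not None:
                    placed.append(refs)
        else:
            placed.append(_merge_run_into_candidate(store, sub_rec, cand, config, report))

    for i in range(len(placed) - 1):
        boundary = point_at_arc(segment.geometry, runs[i].s1 * scale)
        crossing = insert_connector(store, (boundary[0], boundary[1]), [placed[i][1], placed[i + 1][0]], config)
        if crossing.id not in report.crossings:
            report.crossings.append(crossing.id)
    if not placed:
        return None
    return placed[0][0], placed[-1][1]


def _merge_run_into_candidate(
    store: MapStore,
    sub_rec: PathRecord,
    cand: PathRecord,
    config: BuilderConfig,
    report: InsertionReport,
) -> Tuple[EndRef, EndRef]:
    """Merge one matching stretch into its candidate, splitting it as needed."""
    frame = LocalFrame.for_points(sub_rec.geometry, cand.geometry)
    cline = LineString(frame.to_xy(cand.geometry))
    cand_len = path_length(cand)
    cscale = cand_len / cline.length if cline.length > 0 else 1.0
    c0 = float(shapely.line_locate_point(cline, shapely.points(frame.to_xy(sub_rec.geometry[0])))) * cscale
    c1 = float(shapely.line_locate_point(cline, shapely.points(frame.to_xy(sub_rec.geometry[-1])))) * cscale
    reversed_ = c0 > c1
    lo, hi = sorted((c0, c1))
    eps = config.resample_spacing
    lo = 0.0 if lo <= eps else lo
    hi = cand_len if hi >= cand_len - eps else hi

    cand_start_cross = cand.start_crossing
    cand_end_cross = cand.end_crossing

    pre_rec = post_rec = None
    rest = PathRecord(
        geometry=cand.geometry.copy(),
        path_type=cand.path_type,
        properties=dict(cand.properties),
        merge_count=cand.merge_count,
    )
    if lo > 0.0:
        pre_rec, rest = split_path(rest, lo)
    if hi < cand_len:
        rest, post_rec = split_path(rest, hi - lo)

    merged_rec = merge_paths(sub_rec, rest, None, config)

    pre_id = store.add_path(pre_rec) if pre_rec is not None else None
    post_id = store.add_path(post_rec) if post_rec is not None else None
    merged_id = store.add_path(merged_rec)
    report.merged.append(merged_id)
    if pre_id:
        report.created.append(pre_id)
    if post_id:
        report.created.append(post_id)

    # merged geometry follows the inserted segment's direction
    merged_lo_end = "start" if not reversed_ else "end"
    merged_hi_end = "end" if not reversed_ else "start"

    # outer crossings of the candidate survive on the surviving piece
    if cand_start_cross is not None:
        if pre_id is not None:
            store.link(pre_id, "start", cand_start_cross)
        else:
            store.link(merged_id, merged_lo_end, cand_start_cross)
    if cand_end_cross is not None:
        if post_id is not None:
            store.link(post_id, "end", cand_end_cross)
        else:
            store.link(merged_id, merged_hi_end, cand_end_cross)

    # interior split points get connectors
    if pre_id is not None:
        pt = point_at_arc(cand.geometry, lo)
        crossing = insert_connector(store, (pt[0], pt[1]), [(pre_id, "end"), (merged_id, merged_lo_end)], config)
        if crossing.id not in report.crossings:
            report.crossings.append(crossing.id)
    if post_id is not None:
        pt = point_at_arc(cand.geometry, hi)
        crossing = insert_connector(store, (pt[0], pt[1]), [(post_id, "start"), (merged_id, merged_hi_end)], config)
        if crossing.id not in report.crossings:
            report.crossings.append(crossing.id)

    store.delete_path(cand.id)
    report.deleted.append(cand.id)
    return (merged_id, "start"), (merged_id, "end")


def split_in_store(store: MapStore, path_id: str, arc_position: float, config: BuilderConfig = BuilderConfig()) -> Tuple[str, str, str]:
    """Split a stored path in place, joining the parts with a connector.

    Returns (id of first part, id of second part, crossing id).
    """
    record = store.get_path(path_id)
    start_cross, end_cross = record.start_crossing, record.end_crossing
    part_a, part_b = split_path(record, arc_position)
    split_point = part_a.geometry[-1]
    id_a = store.add_path(part_a)
    id_b = store.add_path(part_b)
    # link the parts before deleting the original so its crossings survive
    if start_cross is not None:
        store.link(id_a, "start", start_cross)
    if end_cross is not None:
        store.link(id_b, "end", end_cross)
    store.delete_path(path_id)
    crossing = insert_connector(store, (split_point[0], split_point[1]), [(id_a, "end"), (id_b, "start")], config)
    return id_a, id_b, crossing.id


def prune_unmerged(store: MapStore, min_merges: int) -> List[str]:
    """Remove paths whose merge count never reached ``min_merges``.

    Crossings left without connections disappear with their last path.
    """
    if min_merges < 1:
        raise InvalidInputError("min_merges must be >= 1")
    removed = [pid for pid, rec in store.paths.items() if rec.merge_count < min_merges]
    for pid in removed:
        store.delete_path(pid)
    return removed


# ---------------------------------------------------------------------------
# evaluation


def evaluate_map(constructed: MapStore, truth: MapStore, buffer: float = 5.0) -> Tuple[float, float]:
    """Geometric and topological correctness of a constructed map.

    Geometric correctness is the fraction of constructed path length lying
    within ``buffer`` metres of the reference network; topological
    correctness is the fraction of reference crossings that have a
    constructed crossing within ``buffer`` metres.  A reference without
    crossings scores topological correctness 1 vacuously.
    """
    if not truth.paths:
        raise InvalidInputError("reference map has no paths")
    all_points = [rec.geometry for rec in truth.paths.values()]
    frame = LocalFrame.for_points(*all_points)
    truth_zone = unary_union([LineString(frame.to_xy(rec.geometry)) for rec in truth.paths.values()]).buffer(buffer)
    total = 0.0
    inside = 0.0
    for rec in constructed.paths.values():
        line = LineString(frame.to_xy(rec.geometry))
        total += line.length
        inside += line.intersection(truth_zone).length
    geometric = inside / total if total > 0 else 0.0
    if not truth.crossings:
        topological = 1.0
    else:
        recovered = 0
        for crossing in truth.crossings.values():
            tx, ty = frame.to_xy(np.array(crossing.location))
            for built in constructed.crossings.values():
                bx, by = frame.to_xy(np.array(built.location))
                if np.hypot(tx - bx, ty - by) <= buffer:
                    recovered += 1
                    break
        topological = recovered / len(truth.crossings)
    return float(geometric), float(topological)


# ---------------------------------------------------------------------------
# trace/step conversion

_ACTIVITY_TO_TYPE = {
    ActivityClass.WALK: "walk",
    ActivityClass.STAIRS_UP: "stairs_up",
    ActivityClass.STAIRS_DOWN: "stairs_down",
}

#: A full stride of one leg covers two staircase steps.
_STAIRS_PER_STRIDE = 2


def trace_to_path(fixes: Sequence[GeoFix], path_type: str = "trail", smooth_window: int = 5, properties: Optional[Dict] = None) -> PathRecord:
    """Turn a GPS fix sequence into a path, moving-average smoothing the jitter.

    ``smooth_window`` is the number of fixes averaged per output vertex
    (shrinking near the trace ends so endpoints stay anchored); 1 disables
    smoothing.
    """
    if len(fixes) < 2:
        raise InvalidInputError("need at least 2 fixes for a path")
    coords = np.array([[f.longitude, f.latitude] for f in fixes], dtype=float)
    if smooth_window > 1:
        half = smooth_window // 2
        smoothed = np.empty_like(coords)
        for i in range(len(coords)):
            w = min(half, i, len(coords) - 1 - i)
            smoothed[i] = coords[i - w : i + w + 1].mean(axis=0)
        coords = smoothed
    keep = np.concatenate([[True], np.linalg.norm(np.diff(coords, axis=0), axis=1) > 1e-12])
    coords = coords[keep]
    if coords.shape[0] < 2:
        raise InvalidInputError("trace collapses to a point")
    return PathRecord(geometry=coords, path_type=path_type, properties=dict(properties or {}))


def steps_to_paths(steps: Sequence[ClassifiedStep], min_run: int = 3) -> List[PathRecord]:
    """Group a time-ordered step sequence into activity-typed paths.

    Contiguous runs of the same activity become one path; runs shorter than
    ``min_run`` steps are absorbed into the preceding run (or the following
    one at the start).  Stairs paths get a ``stair_count`` of two staircase
    steps per stride.
    """
    steps = sorted(steps, key=lambda s: s.time)
    if len(steps) < 2:
        return []
    labels = [s.activity for s in steps]
    runs: List[Tuple[int, int, ActivityClass]] = []
    start = 0
    for i in range(1, len(labels) + 1):
        if i == len(labels) or labels[i] != labels[start]:
            runs.append((start, i, labels[start]))
            start = i
    merged_runs: List[List] = []
    for run in runs:
        if merged_runs and (run[1] - run[0]) < min_run:
            merged_runs[-1][1] = run[1]
        elif not merged_runs and (run[1] - run[0]) < min_run and len(runs) > 1:
            merged_runs.append([run[0], run[1], None])  # absorbed by the next run
        else:
            if merged_runs and merged_runs[-1][2] is None:
                merged_runs[-1] = [merged_runs[-1][0], run[1], run[2]]
            else:
                merged_runs.append([run[0], run[1], run[2]])
    paths: List[PathRecord] = []
    for i, (a, b, activity) in enumerate(merged_runs):
        if activity is None:
            continue
        # extend by one step into the next run so consecutive paths share a point
        stop = min(b + 1, len(steps))
        pts = np.array([[s.longitude, s.latitude] for s in steps[a:stop]], dtype=float)
        keep = np.concatenate([[True], np.linalg.norm(np.diff(pts, axis=0), axis=1) > 1e-12])
        pts = pts[keep]
        if pts.shape[0] < 2:
            continue
        path_type = _ACTIVITY_TO_TYPE[activity]
        props = {"stair_count": _STAIRS_PER_STRIDE * (b - a)} if path_type in STAIR_TYPES else {}
        paths.append(PathRecord(geometry=pts, path_type=path_type, properties=props))
    return paths
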