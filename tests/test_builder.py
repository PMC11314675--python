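"""Simplification, matching, splitting, weighted merging and insertion."""

import numpy as np
import pytest
from shapely.geometry import LineString

from stridemap import (
    BuilderConfig,
    InvalidInputError,
    MapStore,
    PathTypeMismatchError,
    evaluate_map,
    insert_connector,
    insert_path,
    match_paths,
    merge_paths,
    path_length,
    prune_unmerged,
    simplify_path,
    split_in_store,
    split_path,
)

CFG = BuilderConfig()


def _segments_cross(p1, p2, q1, q2):
    """Brute-force proper segment crossing test (transversal, not touching)."""

    def orient(a, b, c):
        return np.sign((b[0] - a[0]) * (c[1] - a[1]) - (b[1] - a[1]) * (c[0] - a[0]))

    d1, d2 = orient(q1, q2, p1), orient(q1, q2, p2)
    d3, d4 = orient(p1, p2, q1), orient(p1, p2, q2)
    return d1 * d2 < 0 and d3 * d4 < 0


def _count_self_intersections(xy):
    """Oracle: pairwise scan of non-adjacent segments."""
    n = 0
    for i in range(len(xy) - 1):
        for j in range(i + 2, len(xy) - 1):
            if i == 0 and j == len(xy) - 2 and np.allclose(xy[0], xy[-1]):
                continue  # closed ring endpoints are one point, not a crossing
            if _segments_cross(xy[i], xy[i + 1], xy[j], xy[j + 1]):
                n += 1
    return n


class TestSimplifyPath:
    def test_figure_eight_splits_at_the_crossing(self, mkpath, frame):
        fig8 = [[0, 0], [10, 10], [20, 0], [10, -10], [0, 0], [-10, 10], [-20, 0], [-10, -10], [0, 0]]
        assert _count_self_intersections(np.asarray(fig8, float)) == 0  # crossing is at a shared vertex
        segments = simplify_path(mkpath(fig8), CFG)
        assert len(segments) == 2
        for segment in segments:
            xy = frame.to_xy(segment.geometry)
            assert _count_self_intersections(xy) == 0
        total = sum(path_length(s) for s in segments)
        assert total == pytest.approx(path_length(mkpath(fig8)), rel=0.02)

    def test_crossing_between_vertices_is_split(self, mkpath, frame):
        crossed = [[0, 0], [100, 0], [100, 30], [50, -30]]  # last segment crosses the first
        assert _count_self_intersections(np.asarray(crossed, float)) == 1
        segments = simplify_path(mkpath(crossed), CFG)
        assert len(segments) >= 2
        for segment in segments:
            assert _count_self_intersections(frame.to_xy(segment.geometry)) == 0

    def test_dense_straight_path_downsamples_within_tolerance(self, mkpath, frame):
        dense = np.column_stack([np.arange(0, 100.001, 0.1), np.zeros(1001)])
        out = simplify_path(mkpath(dense), CFG)
        assert len(out) == 1
        simplified = out[0]
        assert simplified.geometry.shape[0] < 50
        xy = frame.to_xy(simplified.geometry)
        assert np.allclose(xy[0], [0, 0], atol=1e-6) and np.allclose(xy[-1], [100, 0], atol=1e-6)
        # deviation oracle: every removed vertex stays within tolerance of the output
        line = LineString(xy)
        deviations = [line.distance(LineString([p, p]).centroid) for p in frame.to_xy(mkpath(dense).geometry)]
        assert max(deviations) <= CFG.simplify_tolerance + 1e-9

    def test_already_simple_path_unchanged(self, mkpath):
        record = mkpath([[0, 0], [50, 10], [100, 0]])
        out = simplify_path(record, CFG)
        assert len(out) == 1
        assert np.allclose(out[0].geometry, record.geometry)

    def test_stair_counts_apportioned_over_pieces(self, mkpath):
        fig8 = [[0, 0], [10, 10], [20, 0], [10, -10], [0, 0], [-10, 10], [-20, 0], [-10, -10], [0, 0]]
        segments = simplify_path(mkpath(fig8, path_type="stairs_up", properties={"stair_count": 21}), CFG)
        assert sum(s.properties["stair_count"] for s in segments) == 21


class TestMatchPaths:
    def test_identical_geometries_fully_match(self, mkpath):
        a = mkpath([[0, 0], [90, 0]])
        result = match_paths(a, mkpath([[0, 0], [90, 0]]), CFG)
        assert result.unmatched == []
        ((s0, s1), (c0, c1)), = result.matched
        assert s0 == pytest.approx(0.0, abs=1e-6)
        assert s1 == pytest.approx(90.0, abs=0.1)
        assert (c0, c1) == pytest.approx((s0, s1), abs=0.1)

    def test_distant_parallel_paths_do_not_match(self, mkpath):
        result = match_paths(mkpath([[0, 0], [90, 0]]), mkpath([[0, 50], [90, 50]]), CFG)
        assert result.matched == []
        assert result.unmatched == [(0.0, pytest.approx(90.0, abs=0.1))]

    def test_perpendicular_crossing_does_not_match(self, mkpath):
        result = match_paths(mkpath([[0, 0], [90, 0]]), mkpath([[45, -45], [45, 45]]), CFG)
        assert result.matched == []

    def test_middle_coincidence_matches_only_the_middle(self, mkpath, frame):
        """Two 90 m paths sharing their middle 30 m at 1 m offset."""
        new = mkpath([[0, 0], [90, 0]])
        cand = mkpath([[30, 31], [30, 1], [60, 1], [60, 31]])
        result = match_paths(new, cand, CFG)
        assert len(result.matched) == 1
        (s0, s1), (c0, c1) = result.matched[0]
        # oracle: brute-force scan at 0.1 m of the distance+heading criterion
        xs = np.arange(0, 90.001, 0.1)
        inside = (np.sqrt(1.0**2) <= CFG.match_distance) & (xs >= 30) & (xs <= 60)
        lo, hi = xs[inside][0], xs[inside][-1]
        tol = 2 * CFG.resample_spacing
        assert s0 == pytest.approx(lo, abs=tol)
        assert s1 == pytest.approx(hi, abs=tol)
        assert (s1 - s0) == pytest.approx(30.0, abs=2 * tol)
        # candidate range covers its middle stretch (arc 30..60 along the U shape)
        assert c0 == pytest.approx(30.0, abs=tol)
        assert c1 == pytest.approx(60.0, abs=tol)

    def test_short_coincidence_below_min_match_length_demoted(self, mkpath):
        cfg = BuilderConfig(min_match_length=10.0)
        new = mkpath([[0, 0], [90, 0]])
        cand = mkpath([[43, 31], [43, 1], [47, 1], [47, 31]])  # only ~4 m coincident
        result = match_paths(new, cand, cfg)
        assert result.matched == []


class TestSplitPath:
    def test_lengths_and_stair_counts_conserved(self, mkpath):
        record = mkpath([[0, 0], [100, 0]], path_type="stairs_up", properties={"stair_count": 20})
        part_a, part_b = split_path(record, 25.0)
        assert path_length(part_a) == pytest.approx(25.0, abs=0.01)
        assert path_length(part_b) == pytest.approx(75.0, abs=0.01)
        assert path_length(part_a) + path_length(part_b) == pytest.approx(path_length(record), abs=0.01)
        assert part_a.properties["stair_count"] + part_b.properties["stair_count"] == 20

    def test_midpoint_split_halves_stairs(self, mkpath):
        record = mkpath([[0, 0], [20, 0]], path_type="stairs_up", properties={"stair_count": 20})
        part_a, part_b = split_path(record, path_length(record) / 2)
        assert part_a.properties["stair_count"] == 10
        assert part_b.properties["stair_count"] == 10

    def test_merge_count_copied_to_both_parts(self, mkpath):
        record = mkpath([[0, 0], [100, 0]], merge_count=4)
        part_a, part_b = split_path(record, 40.0)
        assert part_a.merge_count == part_b.merge_count == 4

    @pytest.mark.parametrize("position", [0.0, -5.0, 1e9])
    def test_split_outside_interior_rejected(self, mkpath, position):
        with pytest.raises(InvalidInputError):
            split_path(mkpath([[0, 0], [100, 0]]), position)


class TestMergePaths:
    def test_identical_copy_keeps_geometry_and_doubles_weight(self, mkpath):
        a = mkpath([[0, 0], [50, 20], [100, 0]])
        b = mkpath([[0, 0], [50, 20], [100, 0]])
        merged = merge_paths(a, b, None, CFG)
        assert merged.merge_count == 2
        assert path_length(merged) == pytest.approx(path_length(a), rel=1e-3)
        assert np.allclose(merged.geometry[0], a.geometry[0], atol=1e-9)

    def test_offset_merge_lands_at_weighted_mean(self, mkpath, frame):
        a = mkpath([[0, 0], [100, 0]], merge_count=3)
        b = mkpath([[0, 4], [100, 4]], merge_count=1)
        merged = merge_paths(a, b, None, CFG)
        ys = frame.to_xy(merged.geometry)[:, 1]
        assert np.all(np.abs(ys - 1.0) < 1e-6)  # (3*0 + 1*4)/4
        assert merged.merge_count == 4

    def test_stair_counts_average_with_merge_weights(self, mkpath):
        a = mkpath([[0, 0], [20, 0]], path_type="stairs_up", properties={"stair_count": 10})
        b = mkpath([[0, 1], [20, 1]], path_type="stairs_up", properties={"stair_count": 12})
        assert merge_paths(a, b, None, CFG).properties["stair_count"] == 11

    def test_antiparallel_stretch_reoriented_before_averaging(self, mkpath, frame):
        a = mkpath([[0, 0], [100, 0]])
        b = mkpath([[100, 2], [0, 2]])
        merged = merge_paths(a, b, None, CFG)
        xy = frame.to_xy(merged.geometry)
        assert np.all(np.abs(xy[:, 1] - 1.0) < 1e-6)
        assert xy[0, 0] == pytest.approx(0.0, abs=1e-6)  # follows a's direction

    def test_type_mismatch_refused(self, mkpath):
        a = mkpath([[0, 0], [100, 0]], path_type="walk")
        b = mkpath([[0, 1], [100, 1]], path_type="stairs_up", properties={"stair_count": 8})
        with pytest.raises(PathTypeMismatchError):
            merge_paths(a, b, None, CFG)
        untyped = BuilderConfig(respect_path_types=False)
        merged = merge_paths(a, b, None, untyped)
        assert merged.merge_count == 2

    def test_merge_order_insensitive_for_full_matches(self, mkpath, frame):
        a = mkpath([[0, 0], [100, 0]])
        b = mkpath([[0, 3], [100, 3]])
        c = mkpath([[0, 6], [100, 6]])
        ab_c = merge_paths(merge_paths(a, b, None, CFG), c, None, CFG)
        ac_b = merge_paths(merge_paths(a, c, None, CFG), b, None, CFG)
        ya = frame.to_xy(ab_c.geometry)[:, 1]
        yb = frame.to_xy(ac_b.geometry)[:, 1]
        assert np.allclose(ya, 3.0, atol=CFG.resample_spacing)
        assert np.allclose(yb, 3.0, atol=CFG.resample_spacing)
        assert ab_c.merge_count == ac_b.merge_count == 3


class TestConnectors:
    def test_t_branch_yields_three_end_crossing(self, mkpath):
        store = MapStore()
        pid = store.add_path(mkpath([[0, 0], [100, 0]], path_type="walk"))
        id_a, id_b, cid = split_in_store(store, pid, 50.0, CFG)
        branch = store.add_path(mkpath([[50, 0], [50, 60]], path_type="walk"))
        crossing = insert_connector(store, tuple(store.get_path(branch).geometry[0]), [(branch, "start")], CFG)
        assert crossing.id == cid  # snapped onto the split-point connector
        assert len(crossing.connections) == 3
        assert store.audit() == []

    def test_nearby_boundary_points_share_one_crossing(self, mkpath):
        store = MapStore()
        p1 = store.add_path(mkpath([[0, 0], [50, 0]]))
        p2 = store.add_path(mkpath([[50.5, 0.3], [100, 0]]))
        c1 = insert_connector(store, tuple(store.get_path(p1).geometry[-1]), [(p1, "end")], CFG)
        c2 = insert_connector(store, tuple(store.get_path(p2).geometry[0]), [(p2, "start")], CFG)
        assert c1.id == c2.id

    def test_dangling_reference_rejected(self, mkpath):
        store = MapStore()
        from stridemap import ConsistencyError

        with pytest.raises(ConsistencyError):
            insert_connector(store, (10.0, 48.0), [("p404", "start")], CFG)


class TestInsertPath:
    def test_first_insert_creates_single_unconnected_path(self, mkpath):
        store = MapStore()
        report = insert_path(store, mkpath([[0, 0], [100, 0]], path_type="walk"), CFG)
        assert len(store.paths) == 1 and len(store.crossings) == 0
        assert len(report.created) == 1 and report.merged == []
        (record,) = store.paths.values()
        assert record.merge_count == 1

    def test_repeated_trace_merges_without_interior_crossings(self, mkpath):
        store = MapStore()
        insert_path(store, mkpath([[0, 0], [100, 0]], path_type="walk"), CFG)
        report = insert_path(store, mkpath([[0, 0], [100, 0]], path_type="walk"), CFG)
        assert len(store.paths) == 1 and len(store.crossings) == 0
        (record,) = store.paths.values()
        assert record.merge_count == 2
        assert len(report.merged) == 1 and len(report.deleted) == 1

    def test_half_shared_trace_splits_and_branches(self, mkpath, frame):
        store = MapStore()
        insert_path(store, mkpath([[0, 0], [100, 0]], path_type="walk"), CFG)
        diverging = np.vstack(
            [
                np.column_stack([np.linspace(0, 50, 26), np.zeros(26)]),
                np.column_stack([50 + np.linspace(2, 50, 25), np.linspace(2, 50, 25)]),
            ]
        )
        insert_path(store, mkpath(diverging, path_type="walk"), CFG)
        assert len(store.paths) == 3
        assert len(store.crossings) == 1
        (crossing,) = store.crossings.values()
        assert len(crossing.connections) == 3
        merged = [r for r in store.paths.values() if r.merge_count == 2]
        assert len(merged) == 1
        assert path_length(merged[0]) == pytest.approx(50.0, abs=3 * CFG.resample_spacing)
        assert store.audit() == []

    def test_typed_paths_do_not_merge_across_types(self, mkpath):
        store = MapStore()
        insert_path(store, mkpath([[0, 0], [100, 0]], path_type="walk"), CFG)
        insert_path(store, mkpath([[0, 0.5], [100, 0.5]], path_type="stairs_up", properties={"stair_count": 10}), CFG)
        assert len(store.paths) == 2
        assert all(r.merge_count == 1 for r in store.paths.values())
        untyped = MapStore()
        cfg = BuilderConfig(respect_path_types=False)
        insert_path(untyped, mkpath([[0, 0], [100, 0]], path_type="walk"), cfg)
        insert_path(untyped, mkpath([[0, 0.5], [100, 0.5]], path_type="stairs_up", properties={"stair_count": 10}), cfg)
        assert len(untyped.paths) == 1

    def test_insertion_is_atomic_on_failure(self, mkpath, monkeypatch):
        store = MapStore()
        insert_path(store, mkpath([[0, 0], [100, 0]], path_type="walk"), CFG)
        before = store.to_geojson()
        import stridemap.builder as bld

        def boom(*args, **kwargs):
            raise RuntimeError("injected failure")

        monkeypatch.setattr(bld, "merge_paths", boom)
        with pytest.raises(RuntimeError):
            insert_path(store, mkpath([[0, 0], [100, 0]], path_type="walk"), CFG)
        assert store.to_geojson() == before


class TestPrune:
    def test_all_singletons_removed(self, mkpath):
        store = MapStore()
        for y in (0, 50, 100):
            insert_path(store, mkpath([[0, y], [100, y]], path_type="walk"), CFG)
        removed = prune_unmerged(store, 2)
        assert len(removed) == 3 and store.paths == {} and store.crossings == {}

    def test_min_merges_one_removes_nothing(self, mkpath):
        store = MapStore()
        insert_path(store, mkpath([[0, 0], [100, 0]], path_type="walk"), CFG)
        assert prune_unmerged(store, 1) == []
        assert len(store.paths) == 1

    def test_invalid_min_merges_rejected(self):
        with pytest.raises(InvalidInputError):
            prune_unmerged(MapStore(), 0)


class TestEvaluateMap:
    def _store_with(self, mkpath, *xys):
        store = MapStore()
        for xy in xys:
            store.add_path(mkpath(xy, path_type="walk"))
        return store

    def test_identical_maps_score_perfectly(self, mkpath):
        truth = self._store_with(mkpath, [[0, 0], [100, 0]])
        from stridemap import Crossing

        cid = truth.add_crossing(Crossing(location=tuple(truth.get_path("p1").geometry[-1])))
        truth.link("p1", "end", cid)
        built = self._store_with(mkpath, [[0, 0], [100, 0]])
        cid2 = built.add_crossing(Crossing(location=tuple(built.get_path("p1").geometry[-1])))
        built.link("p1", "end", cid2)
        assert evaluate_map(built, truth, 5.0) == (1.0, 1.0)

    def test_disjoint_maps_score_zero(self, mkpath):
        truth = self._store_with(mkpath, [[0, 0], [100, 0]])
        built = self._store_with(mkpath, [[0, 500], [100, 500]])
        geometric, _ = evaluate_map(built, truth, 5.0)
        assert geometric == 0.0

    def test_half_inside_scores_half(self, mkpath):
        truth = self._store_with(mkpath, [[0, 0], [100, 0]])
        built = self._store_with(mkpath, [[0, 0], [100, 0]], [[0, 100], [100, 100]])
        geometric, _ = evaluate_map(built, truth, 5.0)
        assert geometric == pytest.approx(0.5, abs=0.02)

    def test_empty_truth_rejected(self, mkpath):
        with pytest.raises(InvalidInputError):
            evaluate_map(self._store_with(mkpath, [[0, 0], [100, 0]]), MapStore(), 5.0)
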