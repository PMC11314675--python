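"""Generators: gait waveforms, ground-truth networks and GPS traces."""

import numpy as np
import pytest

from stridemap import (
    ActivityClass,
    GaitGeneratorParams,
    InvalidInputError,
    LocalFrame,
    TraceGeneratorParams,
    detect_step_events,
    extract_features,
    generate_gait_recording,
    generate_gps_trace,
    generate_labeled_dataset,
    generate_truth_network,
    path_length,
    segment_steps,
)
from stridemap.features import FEATURE_NAMES
from shapely.geometry import LineString


class TestGaitGenerator:
    def test_noise_free_schedule_detects_exact_stride_count(self):
        params = GaitGeneratorParams(seed=0, noise_sd=0.0)
        rec, spans = generate_gait_recording([(ActivityClass.WALK, 10)], params)
        assert len(detect_step_events(rec)) == 10
        assert len(spans) == 1 and spans[0][2] == ActivityClass.WALK

    def test_same_seed_reproduces_recording(self):
        a, _ = generate_gait_recording([(ActivityClass.WALK, 5)], GaitGeneratorParams(seed=1), "S1", "T1")
        b, _ = generate_gait_recording([(ActivityClass.WALK, 5)], GaitGeneratorParams(seed=1), "S1", "T1")
        c, _ = generate_gait_recording([(ActivityClass.WALK, 5)], GaitGeneratorParams(seed=2), "S1", "T1")
        assert np.array_equal(a.thigh.inclination, b.thigh.inclination)
        assert not np.array_equal(a.thigh.inclination, c.thigh.inclination)

    def test_stairs_up_has_larger_thigh_range_than_walk(self):
        """Across ~100 strides the class amplitude ordering must survive noise."""
        ranges = {ActivityClass.WALK: [], ActivityClass.STAIRS_UP: []}
        for cls in ranges:
            for si in range(10):
                rec, _ = generate_gait_recording([(cls, 11)], GaitGeneratorParams(seed=5), f"S{si}", "T0")
                windows = segment_steps(detect_step_events(rec), rec.timestamps)
                idx = FEATURE_NAMES.index("thigh_range")
                ranges[cls].extend(extract_features(rec, w)[idx] for w in windows)
        assert len(ranges[ActivityClass.WALK]) >= 90
        assert np.mean(ranges[ActivityClass.STAIRS_UP]) > np.mean(ranges[ActivityClass.WALK])

    def test_bouts_are_separated_and_labeled(self):
        schedule = [(ActivityClass.WALK, 6), (ActivityClass.STAIRS_DOWN, 6)]
        rec, spans = generate_gait_recording(schedule, GaitGeneratorParams(seed=3))
        assert [s[2] for s in spans] == [ActivityClass.WALK, ActivityClass.STAIRS_DOWN]
        assert spans[1][0] - spans[0][1] >= GaitGeneratorParams().bout_gap - 0.1

    def test_empty_schedule_rejected(self):
        with pytest.raises(InvalidInputError):
            generate_gait_recording([], GaitGeneratorParams(seed=0))

    def test_labeled_dataset_covers_all_classes_and_subjects(self):
        samples = generate_labeled_dataset(n_subjects=3, params=GaitGeneratorParams(seed=8))
        assert {s.subject_id for s in samples} == {"S00", "S01", "S02"}
        assert {s.label for s in samples} == set(ActivityClass)
        walks = sum(1 for s in samples if s.label == ActivityClass.WALK)
        stairs = sum(1 for s in samples if s.label != ActivityClass.WALK)
        assert walks == pytest.approx(stairs, rel=0.25)  # roughly 2:1:1


class TestTruthNetworks:
    def test_corridor_template(self):
        store = generate_truth_network("corridor_with_stairs")
        assert len(store.paths) == 3 and len(store.crossings) == 2
        stairs = [p for p in store.paths.values() if p.path_type == "stairs_up"]
        assert len(stairs) == 2
        assert all(p.properties["stair_count"] == 21 for p in stairs)
        hallway = [p for p in store.paths.values() if p.path_type == "walk"]
        assert path_length(hallway[0]) == pytest.approx(46.0, abs=0.1)

    def test_campus_grid_template(self):
        store = generate_truth_network("campus_grid")
        assert len(store.paths) == 12 and len(store.crossings) == 9

    def test_plus_junction_template(self):
        store = generate_truth_network("plus_junction")
        assert len(store.paths) == 4 and len(store.crossings) == 1
        (crossing,) = store.crossings.values()
        assert len(crossing.connections) == 4

    @pytest.mark.parametrize("template", ["corridor_with_stairs", "campus_grid", "plus_junction"])
    def test_templates_pass_consistency_audit(self, template):
        assert generate_truth_network(template).audit() == []

    def test_unknown_template_rejected(self):
        with pytest.raises(InvalidInputError):
            generate_truth_network("lunar_base")


class TestGpsTraces:
    def _route_distances(self, network, route, params):
        fixes = generate_gps_trace(network, route, params)
        pts = np.array([[f.longitude, f.latitude] for f in fixes])
        geoms = [network.get_path(pid).geometry for pid in route]
        frame = LocalFrame.for_points(*geoms)
        route_line = LineString(np.vstack([frame.to_xy(g) for g in geoms]))
        import shapely

        return shapely.distance(shapely.points(frame.to_xy(pts)), route_line), fixes

    def test_noise_free_trace_follows_route(self):
        net = generate_truth_network("plus_junction")
        pids = sorted(net.paths)
        params = TraceGeneratorParams(seed=0, position_noise_sd=0.0, reflection_probability=0.0)
        d, fixes = self._route_distances(net, [pids[0], pids[1]], params)
        assert d.max() <= 0.1
        times = [f.time for f in fixes]
        assert np.allclose(np.diff(times), params.fix_interval)

    def test_gaussian_noise_tail(self):
        """With sigma = 2 m, ~95% of fixes lie within 4 m of the route."""
        net = generate_truth_network("campus_grid")
        pids = sorted(net.paths)
        d_all = []
        for seed in range(4):
            params = TraceGeneratorParams(seed=seed, position_noise_sd=2.0, reflection_probability=0.0)
            d, _ = self._route_distances(net, pids[:1], params)
            d_all.extend(d)
        frac = np.mean(np.asarray(d_all) <= 4.0)
        assert frac >= 0.85  # half-normal tail 0.954, with binomial slack

    def test_forced_reflection_displaces_a_run(self):
        net = generate_truth_network("plus_junction")
        pids = sorted(net.paths)
        params = TraceGeneratorParams(seed=3, reflection_probability=1.0, reflection_offset=25.0)
        d, _ = self._route_distances(net, [pids[0], pids[1]], params)
        far = d >= 20.0
        assert far.sum() >= 2
        # displaced fixes form a contiguous run
        idx = np.flatnonzero(far)
        assert idx[-1] - idx[0] == len(idx) - 1

    def test_disconnected_route_rejected(self):
        net = generate_truth_network("campus_grid")
        pids = sorted(net.paths)
        # find two edges that share no endpoint
        from stridemap.pathmodel import path_bbox

        with pytest.raises(InvalidInputError):
            # opposite corners of the grid never touch
            horiz = [p for p in pids if abs(net.get_path(p).geometry[0, 1] - net.get_path(p).geometry[1, 1]) < 1e-9]
            a = min(horiz, key=lambda p: path_bbox(net.get_path(p))[1])
            b = max(horiz, key=lambda p: path_bbox(net.get_path(p))[3])
            generate_gps_trace(net, [a, b], TraceGeneratorParams(seed=0))

    def test_trace_reproducible_given_seed(self):
        net = generate_truth_network("plus_junction")
        pids = sorted(net.paths)
        params = TraceGeneratorParams(seed=9)
        a = generate_gps_trace(net, [pids[0]], params)
        b = generate_gps_trace(net, [pids[0]], params)
        assert [(f.latitude, f.longitude, f.time) for f in a] == [(f.latitude, f.longitude, f.time) for f in b]
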