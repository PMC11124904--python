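import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from circumkin import kinematics as K
from circumkin.kinematics import (
    PlanarPath,
    UndefinedAngleError,
    classify_direction,
    circumnutation_center_distance,
    count_switches,
    label_phase,
    leaf_kinematics,
    planar,
    raster_area,
    raster_cells,
    segment_circumnutations,
    speed_profile,
    turning_angle_sum,
)
from circumkin.simulate import PlantSimConfig, simulate_plant

from conftest import circle_path

TWO_PI = 2.0 * np.pi


class TestSpeedProfile:
    def test_uniform_linear_motion(self):
        times = np.arange(5) * 3.0
        pos = np.c_[np.arange(5.0), np.zeros(5), np.zeros(5)]  # 1 mm per step
        speeds, accels = speed_profile(times, pos)
        np.testing.assert_allclose(speeds, 1.0 / 3.0)
        np.testing.assert_allclose(accels, 0.0)

    def test_stationary_marker(self):
        speeds, _ = speed_profile(np.arange(4) * 3.0, np.zeros((4, 3)))
        np.testing.assert_array_equal(speeds, 0.0)

    def test_uniform_circular_motion_matches_chord_formula(self):
        R, T, dt = 10.0, 100.0, 3.0
        t = np.arange(0.0, 300.0, dt)
        pos = np.c_[R * np.cos(TWO_PI * t / T), np.zeros_like(t), R * np.sin(TWO_PI * t / T)]
        speeds, _ = speed_profile(t, pos)
        expected = 2.0 * R * np.sin(np.pi * dt / T) / dt  # chord length per step
        np.testing.assert_allclose(speeds.mean(), expected, rtol=1e-12)

    def test_zero_dt_rejected(self):
        with pytest.raises(ValueError):
            speed_profile(np.array([0.0, 0.0, 3.0]), np.zeros((3, 3)))


class TestTurningAngleSum:
    def test_closed_ccw_circle_is_two_pi(self):
        assert abs(turning_angle_sum(circle_path(200)) - TWO_PI) < 1e-6

    def test_closed_cw_circle_is_minus_two_pi(self):
        assert abs(turning_angle_sum(circle_path(200, clockwise=True)) + TWO_PI) < 1e-6

    def test_hexagon_exterior_angles(self):
        hexagon = circle_path(6)
        np.testing.assert_allclose(turning_angle_sum(hexagon), TWO_PI, atol=1e-12)

    def test_collinear_path_sums_to_zero(self):
        path = PlanarPath(np.arange(5) * 3.0, np.c_[np.arange(5.0), np.zeros(5)])
        assert turning_angle_sum(path) == 0.0

    def test_fewer_than_two_displacements_raises(self):
        path = PlanarPath(np.arange(3) * 3.0, np.zeros((3, 2)))
        with pytest.raises(UndefinedAngleError):
            turning_angle_sum(path)

    def test_rotation_and_translation_invariant(self):
        rng = np.random.default_rng(0)
        pts = rng.normal(size=(40, 2)).cumsum(axis=0)
        path = PlanarPath(np.arange(40) * 3.0, pts)
        base = turning_angle_sum(path)
        theta = 0.7
        rot = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
        moved = PlanarPath(path.times, pts @ rot.T + np.array([13.0, -4.0]))
        np.testing.assert_allclose(turning_angle_sum(moved), base, atol=1e-9)


class TestClassifyDirection:
    @pytest.mark.parametrize(
        "value,label",
        [
            (6.0, "counterclockwise"),
            (-5.5, "clockwise"),
            (0.0, "none"),
            (TWO_PI - 1.1999, "counterclockwise"),  # just inside the band
            (TWO_PI + 1.1999, "counterclockwise"),
            (-(TWO_PI - 1.1999), "clockwise"),
            (TWO_PI + 1.2001, "none"),  # just outside
        ],
    )
    def test_rule(self, value, label):
        assert classify_direction(value) == label

    @given(st.floats(-20.0, 20.0))
    @settings(max_examples=200, deadline=None)
    def test_exactly_one_label(self, s):
        label = classify_direction(s)
        in_ccw = abs(s - TWO_PI) <= 1.2
        in_cw = abs(s + TWO_PI) <= 1.2
        assert label == ("counterclockwise" if in_ccw else "clockwise" if in_cw else "none")


class TestSegmentation:
    def test_three_concatenated_circles(self):
        m = 60
        theta = TWO_PI * np.arange(3 * m + 1) / m
        path = PlanarPath(np.arange(3 * m + 1) * 3.0, 10 * np.c_[np.cos(theta), np.sin(theta)])
        ranges = segment_circumnutations(path)
        assert len(ranges) == 3
        for r in ranges:
            assert abs(abs(turning_angle_sum(path, r)) - TWO_PI) < 1.2

    def test_half_circle_yields_no_loop(self):
        theta = np.pi * np.arange(31) / 30
        path = PlanarPath(np.arange(31) * 3.0, 10 * np.c_[np.cos(theta), np.sin(theta)])
        assert segment_circumnutations(path) == []

    def test_ranges_ordered_and_disjoint(self):
        m = 50
        theta = TWO_PI * np.arange(5 * m) / m
        path = PlanarPath(np.arange(5 * m) * 3.0, 15 * np.c_[np.cos(theta), np.sin(theta)])
        ranges = segment_circumnutations(path)
        for (s0, e0), (s1, e1) in zip(ranges, ranges[1:]):
            assert s0 < e0 <= s1 < e1

    def test_simulated_noiseless_leaves_recovered_exactly(self, noiseless_plant):
        rec = noiseless_plant.recording
        truth = {l["leaf_ordinal"]: l["n_loops"] for l in noiseless_plant.truth["leaves"]}
        for window in rec.windows_for("apex"):
            lk = leaf_kinematics(
                rec.trajectories["apex"], window, rec.origin_xz, rec.condition
            )
            assert lk.n_circumnutations == truth[window.leaf_ordinal]
            assert all(c.direction == "counterclockwise" for c in lk.circumnutations)


class TestCenterDistance:
    def test_three_four_five(self):
        theta = TWO_PI * np.arange(50) / 50
        pts = np.c_[3 + np.cos(theta), 4 + np.sin(theta)]
        path = PlanarPath(np.arange(50) * 3.0, pts)
        center, dist = circumnutation_center_distance(path, (0, 50), (0.0, 0.0))
        np.testing.assert_allclose(center, (3.0, 4.0), atol=1e-9)
        np.testing.assert_allclose(dist, 5.0, atol=1e-9)

    def test_symmetric_cloud_distance_zero(self):
        pts = np.array([[1.0, 0.0], [-1.0, 0.0], [0.0, 2.0], [0.0, -2.0]])
        _, dist = circumnutation_center_distance(
            PlanarPath(np.arange(4) * 3.0, pts), (0, 4), (0.0, 0.0)
        )
        assert dist == 0.0

    def test_center_is_coordinate_mean(self):
        rng = np.random.default_rng(3)
        pts = rng.normal(size=(100, 2)) * 7 + [5, -2]
        path = PlanarPath(np.arange(100) * 3.0, pts)
        center, _ = circumnutation_center_distance(path, (10, 90), (0.0, 0.0))
        np.testing.assert_allclose(center, pts[10:90].mean(axis=0), rtol=1e-12)

    def test_translation_equivariance(self):
        rng = np.random.default_rng(4)
        pts = rng.normal(size=(30, 2)).cumsum(axis=0)
        path = PlanarPath(np.arange(30) * 3.0, pts)
        _, d0 = circumnutation_center_distance(path, (0, 30), (1.0, 2.0))
        shifted = PlanarPath(path.times, pts + [10.0, -3.0])
        _, d1 = circumnutation_center_distance(shifted, (0, 30), (11.0, -1.0))
        np.testing.assert_allclose(d0, d1, rtol=1e-12)


def _shapely_cells(pts: np.ndarray, pixel: float) -> set[tuple[int, int]]:
    """Independent rasterization oracle via exact segment/cell intersection."""
    from shapely.geometry import LineString, Point, box

    if len(pts) == 1 or np.allclose(pts, pts[0]):
        geom = Point(pts[0] / pixel)
    else:
        geom = LineString(np.asarray(pts, dtype=float) / pixel)
    minx, miny, maxx, maxy = geom.bounds
    cells = set()
    for i in range(int(np.floor(minx)) - 1, int(np.floor(maxx)) + 2):
        for j in range(int(np.floor(miny)) - 1, int(np.floor(maxy)) + 2):
            if geom.intersects(box(i, j, i + 1, j + 1)) and not geom.touches(
                box(i, j, i + 1, j + 1)
            ):
                cells.add((i, j))
    return cells


class TestRasterArea:
    def test_stationary_point_is_one_pixel(self):
        path = PlanarPath(np.array([0.0, 3.0]), np.array([[2.3, 7.1], [2.3, 7.1]]))
        assert raster_area(path, pixel_size=0.5) == 0.25

    def test_axis_aligned_segment(self):
        path = PlanarPath(np.array([0.0, 3.0]), np.array([[0.0, 0.5], [10.0, 0.5]]))
        assert raster_area(path, pixel_size=1.0) == 11.0

    def test_matches_exact_intersection_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            pts = rng.uniform(-8, 8, size=(6, 2))
            ours = raster_cells(pts, 1.0)
            oracle = _shapely_cells(pts, 1.0)
            assert ours == oracle

    def test_monotone_in_path_length(self):
        rng = np.random.default_rng(6)
        pts = rng.uniform(0, 30, size=(20, 2))
        counts = [len(raster_cells(pts[: k + 2], 1.0)) for k in range(18)]
        assert all(a <= b for a, b in zip(counts, counts[1:]))

    def test_halving_pixel_never_decreases_count(self):
        rng = np.random.default_rng(7)
        pts = rng.uniform(0, 20, size=(12, 2))
        assert len(raster_cells(pts, 0.5)) >= len(raster_cells(pts, 1.0))


class TestCountSwitches:
    @pytest.mark.parametrize(
        "labels,expected",
        [
            (["counterclockwise"] * 2 + ["clockwise", "counterclockwise"], (1, 1)),
            (["counterclockwise"] * 5, (0, 0)),
            (["none", "clockwise", "none", "counterclockwise"], (0, 1)),
            ([], (0, 0)),
            (["none", "none"], (0, 0)),
        ],
    )
    def test_rule(self, labels, expected):
        assert count_switches(labels) == expected

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError):
            count_switches(["upward"])


class TestLabelPhase:
    @pytest.mark.parametrize("t,phase", [(0.0, "PRE"), (4999.0, "PRE"), (5000.0, "POST"), (9000.0, "POST")])
    def test_boundary(self, t, phase):
        assert label_phase(t) == phase

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            label_phase(-1.0)


class TestLeafKinematics:
    def test_movement_time_is_window_span(self, noiseless_plant):
        rec = noiseless_plant.recording
        window = rec.windows_for("apex")[0]
        lk = leaf_kinematics(rec.trajectories["apex"], window, rec.origin_xz, rec.condition)
        assert lk.movement_time_min == window.span_min
        assert lk.phase == ("PRE" if window.start_time < 5000 else "POST")

    def test_switch_counts_match_injected_flips(self, noiseless_flip_plant):
        rec = noiseless_flip_plant.recording
        truth = {l["leaf_ordinal"]: (l["n_switches_cw"], l["n_switches_ccw"])
                 for l in noiseless_flip_plant.truth["leaves"]}
        for window in rec.windows_for("apex"):
            lk = leaf_kinematics(rec.trajectories["apex"], window, rec.origin_xz, rec.condition)
            assert (lk.n_switches_cw, lk.n_switches_ccw) == truth[window.leaf_ordinal]

    def test_empty_window_errors(self, noiseless_plant):
        from circumkin.io import LeafWindow

        rec = noiseless_plant.recording
        with pytest.raises(ValueError):
            leaf_kinematics(
                rec.trajectories["apex"],
                LeafWindow(9, "apex", 1e6, 2e6),
                rec.origin_xz,
                rec.condition,
            )

    def test_center_and_speed_match_generator_truth(self):
        """Closure: noiseless loop centers and mean speed equal the
        generating values (chord formula including vertical growth)."""
        cfg = PlantSimConfig(noise_sd_mm=0.0, seed=1)
        sp = simulate_plant(cfg)
        rec = sp.recording
        leaf = sp.truth["leaves"][3]  # a POST leaf, no flips
        window = [w for w in rec.windows_for("apex") if w.leaf_ordinal == 4][0]
        lk = leaf_kinematics(rec.trajectories["apex"], window, rec.origin_xz, rec.condition)
        R, T = leaf["radius_mm"], leaf["period_min"]
        dt = cfg.sampling_step_min
        chord = 2 * R * np.sin(np.pi * dt / T)
        vert = cfg.vertical_growth_mm_per_min * dt
        expected_speed = np.hypot(chord, vert) / dt
        for c in lk.circumnutations:
            np.testing.assert_allclose(c.mean_speed_mm_min, expected_speed, rtol=1e-6)
            np.testing.assert_allclose(
                c.center_xz_mm, leaf["center_xz_mm"], atol=0.05 * R
            )
        np.testing.assert_allclose(
            [c.center_distance_mm for c in lk.circumnutations],
            leaf["center_distance_mm"],
            rtol=0.05,
        )

    def test_loop_measures_invariant_under_rotation(self, noiseless_plant):
        """Rotating the horizontal plane must not change loop count,
        turning sums or durations; the raster footprint may shift by a few
        boundary pixels only."""
        rec = noiseless_plant.recording
        traj = rec.trajectories["apex"]
        window = rec.windows_for("apex")[2]
        lk0 = leaf_kinematics(traj, window, rec.origin_xz, rec.condition)
        theta = 0.61
        rot = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
        pos = traj.positions.copy()
        pos[:, [0, 2]] = pos[:, [0, 2]] @ rot.T
        from circumkin.io import MarkerTrajectory

        rotated = MarkerTrajectory(traj.plant_id, "apex", traj.times, pos)
        lk1 = leaf_kinematics(rotated, window, (0.0, 0.0), rec.condition)
        assert lk1.n_circumnutations == lk0.n_circumnutations
        for a, b in zip(lk0.circumnutations, lk1.circumnutations):
            np.testing.assert_allclose(b.turning_sum_rad, a.turning_sum_rad, atol=1e-6)
            assert b.duration_min == a.duration_min
            assert abs(b.area_mm2 - a.area_mm2) / a.area_mm2 < 0.2


class TestPlanar:
    def test_projection_drops_vertical_axis(self):
        from circumkin.io import MarkerTrajectory

        traj = MarkerTrajectory(
            "P", "apex", [0.0, 3.0], np.array([[1.0, 2.0, 3.0], [4.0, 5.0, 6.0]])
        )
        path = planar(traj)
        np.testing.assert_array_equal(path.points, [[1.0, 3.0], [4.0, 6.0]])

    def test_vertical_only_motion_is_constant_planar(self):
        from circumkin.io import MarkerTrajectory

        pos = np.c_[np.ones(5), np.arange(5.0), np.full(5, 2.0)]
        path = planar(MarkerTrajectory("P", "apex", np.arange(5) * 3.0, pos))
        assert np.ptp(path.points, axis=0).max() == 0.0
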