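"""Life-space feature catalogue: geometry, locations, time budgets."""

import numpy as np
import pandas as pd
import pytest
from shapely.geometry import Polygon

from mobitrace import features as ft
from mobitrace.geo import LocalProjection, haversine
from mobitrace.stopgo import ClassifierParams, StopInterval, run_stop_go
from mobitrace.synthetic import SimConfig, simulate_study

T0 = pd.Timestamp("2022-03-01T00:00:00Z")


def stop_at(proj, x, y, start_h, dur_h):
    lat, lon = proj.inverse(x, y)
    start = T0 + pd.Timedelta(hours=start_h)
    end = start + pd.Timedelta(hours=dur_h)
    return StopInterval(start=start, end=end, centroid_lat=float(lat),
                        centroid_lon=float(lon), duration_s=dur_h * 3600.0,
                        member_count=10, first_idx=0, last_idx=9)


class TestClusterLocations:
    def test_three_stops_one_point_one_cluster(self, proj):
        stops = [stop_at(proj, 0, 0, 8, 1), stop_at(proj, 0, 0, 10, 1),
                 stop_at(proj, 0, 0, 12, 1)]
        clusters = ft.cluster_locations(stops)
        assert len(clusters) == 1
        assert clusters[0].visit_count == 3

    def test_distant_stops_make_separate_clusters(self, proj):
        stops = [stop_at(proj, 0, 0, 8, 1), stop_at(proj, 500, 0, 10, 1)]
        assert len(ft.cluster_locations(stops)) == 2

    def test_chain_matches_brute_force_greedy_replay(self, proj):
        # A-B-C each 80 m apart: replay the greedy rule independently
        stops = [stop_at(proj, 0, 0, 8, 1), stop_at(proj, 80, 0, 10, 1),
                 stop_at(proj, 160, 0, 12, 1)]
        clusters = ft.cluster_locations(stops, 100.0)
        # independent replay with dwell-weighted centroids
        replay = []  # (lat, lon, dwell, members)
        for i, s in enumerate(stops):
            for c in replay:
                if haversine(c[0], c[1], s.centroid_lat, s.centroid_lon) <= 100.0:
                    w = c[2] + s.duration_s
                    c[0] = (c[0] * c[2] + s.centroid_lat * s.duration_s) / w
                    c[1] = (c[1] * c[2] + s.centroid_lon * s.duration_s) / w
                    c[2] = w
                    c[3].append(i)
                    break
            else:
                replay.append([s.centroid_lat, s.centroid_lon, s.duration_s, [i]])
        assert len(clusters) == len(replay)
        for got, exp in zip(clusters, replay):
            assert got.member_stop_ids == exp[3]
            assert got.lat == pytest.approx(exp[0])


class TestDetectHome:
    def test_single_cluster_is_home(self, proj):
        stops = [stop_at(proj, 0, 0, 8, 2)]
        clusters = ft.cluster_locations(stops)
        assert ft.detect_home(clusters, stops).location_id == 0

    def test_night_dwell_wins_over_daytime(self, proj):
        night = [stop_at(proj, 0, 0, 22, 9),       # 22:00-07:00, covers the night
                 stop_at(proj, 0, 0, 46, 9)]
        day = [stop_at(proj, 2000, 0, 9, 12),      # long daytime presence
               stop_at(proj, 2000, 0, 33, 12)]
        stops = sorted(night + day, key=lambda s: s.start)
        clusters = ft.cluster_locations(stops)
        home = ft.detect_home(clusters, stops)
        assert haversine(home.lat, home.lon, night[0].centroid_lat,
                         night[0].centroid_lon) < 1.0

    def test_configured_coordinates_override_dwell(self, proj):
        stops = [stop_at(proj, 0, 0, 1, 6), stop_at(proj, 3000, 0, 10, 1)]
        clusters = ft.cluster_locations(stops)
        lat, lon = proj.inverse(3000.0, 0.0)
        cfg = ft.FeatureConfig(home_coords=(float(lat), float(lon)))
        home = ft.detect_home(clusters, stops, cfg)
        assert home.location_id == 1


class TestHull:
    def test_square_closed_form(self, proj):
        lat, lon = proj.inverse(np.array([0.0, 100, 100, 0]),
                                np.array([0.0, 0, 100, 100]))
        perim, area, comp, _ = ft.convex_hull_metrics(lat, lon, proj)
        assert perim == pytest.approx(400.0, rel=1e-4)
        assert area == pytest.approx(10_000.0, rel=1e-4)
        assert comp == pytest.approx(np.pi / 4.0, rel=1e-4)

    def test_collinear_points_have_zero_area(self, proj):
        lat, lon = proj.inverse(np.arange(5) * 50.0, np.zeros(5))
        _, area, comp, _ = ft.convex_hull_metrics(lat, lon, proj)
        assert area == 0.0
        assert np.isnan(comp)

    def test_circle_compactness_approaches_one(self, proj):
        th = np.linspace(0, 2 * np.pi, 1000, endpoint=False)
        lat, lon = proj.inverse(500 * np.cos(th), 500 * np.sin(th))
        _, _, comp, _ = ft.convex_hull_metrics(lat, lon, proj)
        assert comp == pytest.approx(1.0, rel=0.01)

    def test_hull_contains_every_input_point(self, proj):
        rng = np.random.default_rng(2)
        x, y = rng.normal(0, 300, 200), rng.normal(0, 300, 200)
        lat, lon = proj.inverse(x, y)
        *_, hull = ft.convex_hull_metrics(lat, lon, proj)
        from shapely.geometry import Point
        px, py = proj.forward(lat, lon)
        assert all(hull.buffer(1e-6).contains(Point(a, b)) for a, b in zip(px, py))


def khachiyan_mvee_area(points: np.ndarray, tol: float = 1e-4) -> float:
    """Brute-force minimum-volume enclosing ellipse area (independent oracle)."""
    n, d = points.shape
    Q = np.column_stack([points, np.ones(n)])
    u = np.full(n, 1.0 / n)
    err = 1.0
    while err > tol:
        X = Q.T @ (Q * u[:, None])
        M = np.einsum("ij,jk,ik->i", Q, np.linalg.inv(X), Q)
        j = int(np.argmax(M))
        step = (M[j] - d - 1) / ((d + 1) * (M[j] - 1))
        nu = u * (1 - step)
        nu[j] += step
        err = float(np.linalg.norm(nu - u))
        u = nu
    c = u @ points
    A = np.linalg.inv(points.T @ (points * u[:, None]) - np.outer(c, c)) / d
    return float(np.pi / np.sqrt(np.linalg.det(A)))


class TestStandardEllipse:
    def test_identical_points_give_zero(self, proj):
        lat, lon = proj.inverse(np.zeros(20), np.zeros(20))
        assert ft.standard_ellipse_area(lat, lon, proj) == 0.0

    def test_collinear_points_give_zero(self, proj):
        lat, lon = proj.inverse(np.arange(20) * 10.0, np.zeros(20))
        assert ft.standard_ellipse_area(lat, lon, proj) == 0.0

    def test_uniform_rectangle_matches_covering_ellipse_oracle(self, proj):
        rng = np.random.default_rng(1)
        pts = rng.uniform([-400, -150], [400, 150], (2000, 2))
        lat, lon = proj.inverse(pts[:, 0], pts[:, 1])
        area = ft.standard_ellipse_area(lat, lon, proj)
        oracle = khachiyan_mvee_area(pts)
        assert area == pytest.approx(oracle, rel=0.15)

    def test_rotation_invariance(self, proj):
        rng = np.random.default_rng(1)
        pts = rng.normal(0, [300, 80], (500, 2))
        th = 0.7
        rot = pts @ np.array([[np.cos(th), np.sin(th)],
                              [-np.sin(th), np.cos(th)]])
        a1 = ft.standard_ellipse_area(*proj.inverse(pts[:, 0], pts[:, 1]), proj)
        a2 = ft.standard_ellipse_area(*proj.inverse(rot[:, 0], rot[:, 1]), proj)
        assert a2 == pytest.approx(a1, rel=1e-6)


class TestDailyPathArea:
    @staticmethod
    def straight_trip(proj, length_m, offset_x=0.0, n=101):
        lat, lon = proj.inverse(offset_x + np.zeros(n), np.linspace(0, length_m, n))
        return pd.DataFrame({"lat": lat, "lon": lon})

    def test_capsule_closed_form(self, proj):
        path = self.straight_trip(proj, 1000.0)
        area = ft.daily_path_area([path], proj, 200.0)
        expected = 2 * 200 * 1000 + np.pi * 200 ** 2
        assert area == pytest.approx(expected, rel=0.01)

    def test_union_is_idempotent(self, proj):
        path = self.straight_trip(proj, 1000.0)
        one = ft.daily_path_area([path], proj, 200.0)
        two = ft.daily_path_area([path, path.copy()], proj, 200.0)
        assert two == pytest.approx(one)

    def test_disjoint_trips_sum(self, proj):
        a = self.straight_trip(proj, 800.0)
        b = self.straight_trip(proj, 800.0, offset_x=5000.0)
        both = ft.daily_path_area([a, b], proj, 200.0)
        assert both == pytest.approx(ft.daily_path_area([a], proj, 200.0)
                                     + ft.daily_path_area([b], proj, 200.0))

    def test_no_trips_zero(self, proj):
        assert ft.daily_path_area([], proj) == 0.0


class TestRevisitedLifeSpace:
    unit = Polygon([(0, 0), (100, 0), (100, 100), (0, 100)])

    def test_identical_hulls_are_fully_revisited(self):
        pct, avg = ft.revisited_life_space({1: self.unit, 2: self.unit})
        assert pct[1] == pytest.approx(100.0)
        assert avg == pytest.approx(100.0)

    def test_disjoint_hulls_are_zero(self):
        far = Polygon([(1000, 0), (1100, 0), (1100, 100), (1000, 100)])
        pct, avg = ft.revisited_life_space({1: self.unit, 2: far})
        assert pct[1] == 0.0 and avg == 0.0

    def test_half_overlapping_squares(self):
        shifted = Polygon([(50, 0), (150, 0), (150, 100), (50, 100)])
        pct, avg = ft.revisited_life_space({1: self.unit, 2: shifted})
        assert pct[1] == pytest.approx(50.0)
        assert pct[2] == pytest.approx(50.0)

    def test_missing_hull_day_gets_missing_marker(self):
        pct, avg = ft.revisited_life_space({1: self.unit, 2: None})
        assert np.isnan(pct[2])


class TestModeSplitAndEntropy:
    @staticmethod
    def trip_with_speed(kmh):
        from mobitrace.stopgo import TripInterval
        return TripInterval(start=T0, end=T0 + pd.Timedelta(minutes=10),
                            path=pd.DataFrame(), length_m=kmh / 3.6 * 600,
                            median_speed_kmh=float(kmh), first_idx=0, last_idx=1)

    @pytest.mark.parametrize("kmh,expected", [
        (4.0, ft.FOOT_BIKE), (50.0, ft.VEHICLE), (20.0, ft.FOOT_BIKE)])
    def test_median_speed_thresholding(self, kmh, expected):
        assert ft.mode_split(self.trip_with_speed(kmh), 20.0) == expected

    def test_single_location_entropy_zero(self):
        assert ft.location_entropy({0: 3600.0}) == 0.0

    def test_two_equal_locations_entropy_ln2(self):
        assert ft.location_entropy({0: 100.0, 1: 100.0}) == pytest.approx(np.log(2))

    def test_entropy_matches_direct_summation(self):
        dwell = {0: 3600.0, 1: 7200.0, 2: 10800.0}
        p = np.array([1, 2, 3]) / 6.0
        assert ft.location_entropy(dwell) == pytest.approx(float(-(p * np.log(p)).sum()))

    def test_entropy_bounded_by_log_k(self):
        rng = np.random.default_rng(0)
        dwell = {k: float(v) for k, v in enumerate(rng.uniform(10, 1000, 8))}
        h = ft.location_entropy(dwell)
        assert 0.0 <= h <= np.log(8) + 1e-12

    def test_empty_dwell_map_is_missing(self):
        assert np.isnan(ft.location_entropy({}))


class TestRevisitedPaths:
    def test_out_and_back_counts_as_revisited(self):
        assert ft.revisited_paths_pct([(0, 1), (0, 1)]) == 100.0

    def test_all_distinct_pairs_zero(self):
        assert ft.revisited_paths_pct([(0, 1), (0, 2), (1, 2)]) == 0.0

    def test_two_of_three(self):
        pct = ft.revisited_paths_pct([(0, 1), (0, 1), (0, 2)])
        assert pct == pytest.approx(100.0 * 2 / 3)

    def test_edge_trips_excluded(self):
        assert ft.revisited_paths_pct([None, (0, 1), (0, 1)]) == 100.0


class TestDailyFeatures:
    def test_synthetic_week_matches_truth_bookkeeping(self):
        cfg = SimConfig(seed=8, n_days=4, gps_noise_sigma_m=0.0,
                        dropout_prob=0.0, short_dwell_prob=0.0)
        study = simulate_study(cfg)
        stops, trips, labeled = run_stop_go(study.gps, study.accel)
        daily = ft.compute_daily_features(labeled, stops, trips)
        truth = study.truth_features
        assert len(daily) == len(truth)
        for k in range(len(daily)):
            got, exp = daily.iloc[k], truth.iloc[k]
            assert got["n_locations"] == exp["n_locations"]
            assert got["n_unique_locations"] == exp["n_unique_locations"]
            assert got["n_revisited_locations"] == exp["n_revisited_locations"]
            # interval boundaries are quantised to the 10 s sampling grid
            assert got["time_at_home_s"] == pytest.approx(exp["time_at_home_s"], abs=120)
            assert got["time_out_of_home_s"] == pytest.approx(
                exp["time_out_of_home_s"], abs=120)
            assert got["time_foot_bike_s"] == pytest.approx(
                exp["time_foot_bike_s"], abs=300)
            assert got["time_vehicle_s"] == pytest.approx(exp["time_vehicle_s"], abs=300)
            assert got["max_distance_from_home_m"] == pytest.approx(
                exp["max_distance_from_home_m"], rel=0.02)
            assert got["location_entropy"] == pytest.approx(
                exp["location_entropy"], abs=0.05)
            assert got["time_most_moved"] == exp["time_most_moved"]
            if exp["first_move_time"] is not None:
                got_s = pd.Timedelta(got["first_move_time"]).total_seconds()
                exp_s = pd.Timedelta(exp["first_move_time"]).total_seconds()
                assert abs(got_s - exp_s) <= 60.0

    def test_time_budget_partition_and_bounds(self, small_study):
        stops, trips, labeled = run_stop_go(small_study.gps, small_study.accel)
        daily = ft.compute_daily_features(labeled, stops, trips)
        for _, row in daily.iterrows():
            total = row["time_at_home_s"] + row["time_out_of_home_s"]
            assert 0.0 <= total <= 86_400.0 + 1e-6
            assert row["n_unique_locations"] <= row["n_locations"]
            if np.isfinite(row["daily_revisited_life_space_pct"]):
                assert 0.0 <= row["daily_revisited_life_space_pct"] <= 100.0

    def test_day_entirely_at_home(self, xy_gps):
        rng = np.random.default_rng(4)
        t = np.arange(0, 86_400, 10.0)
        gps = xy_gps(t, rng.normal(0, 8, len(t)), rng.normal(0, 8, len(t)),
                     start="2022-03-01T00:00:00Z")
        stops, trips, labeled = run_stop_go(gps, None,
                                            ClassifierParams(use_motion=False))
        daily = ft.compute_daily_features(labeled, stops, trips)
        row = daily.iloc[0]
        assert row["time_out_of_home_s"] == 0.0
        assert row["n_locations"] == 1
        assert row["location_entropy"] == 0.0
        assert row["first_move_time"] is None
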