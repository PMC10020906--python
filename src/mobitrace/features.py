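"""Life-space mobility variables computed from samples, stops and trips.

One row per participant-day covering the full variable catalogue: distances
from home, convex-hull life space (perimeter, area, Polsby-Popper
compactness), robust standard deviational ellipse area, 200 m-buffered
daily path area, revisited life space, location counts and entropy, time
budgets (at home / out of home / on foot or bike / in vehicle), first-move
time and the most-active time of day.

All planar geometry is computed in a single study-wide azimuthal
equidistant projection (see :mod:`mobitrace.geo`) and delegated to shapely.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import entropy as _shannon_entropy
from shapely.geometry import LineString, MultiPoint, Point
from shapely.ops import unary_union

from .geo import LocalProjection, haversine
from .stopgo import StopInterval, TripInterval

logger = logging.getLogger(__name__)

FOOT_BIKE = "foot_bike"
VEHICLE = "vehicle"

#: local-time trip-count bins for the "time most moved" variable
DAY_BINS = {"morning": (5, 11), "noon": (11, 17), "evening": (17, 23)}

#: column order of the daily-features table
DAILY_COLUMNS = [
    "date", "max_distance_from_home_m", "avg_distance_from_home_m",
    "ellipse_area_m2", "hull_perimeter_m", "hull_area_m2", "hull_compactness",
    "daily_revisited_life_space_pct", "daily_path_area_m2",
    "n_locations", "n_revisited_locations", "n_unique_locations",
    "time_out_of_home_s", "time_foot_bike_s", "time_vehicle_s", "time_at_home_s",
    "first_move_time", "time_most_moved", "revisited_paths_pct", "location_entropy",
]


@dataclass
class LocationCluster:
    """A distinct visited place: one or more stops within a common radius."""

    location_id: int
    lat: float
    lon: float
    member_stop_ids: list[int] = field(default_factory=list)
    total_dwell_s: float = 0.0

    @property
    def visit_count(self) -> int:
        return len(self.member_stop_ids)


@dataclass
class FeatureConfig:
    """Settings for the daily-feature computation."""

    tz: str = "UTC"
    cluster_radius_m: float = 100.0
    mode_threshold_kmh: float = 20.0
    path_buffer_m: float = 200.0
    home_coords: Optional[tuple[float, float]] = None
    night_hours: tuple[int, int] = (0, 6)


# ---------------------------------------------------------------------------
# locations and home


def cluster_locations(stops: Sequence[StopInterval],
                      radius_m: float = 100.0) -> list[LocationCluster]:
    """Greedy sequential clustering of stop centroids into locations.

    In time order, each stop joins the first existing cluster whose centroid
    lies within ``radius_m``, else it founds a new cluster.  Cluster
    centroids are dwell-weighted means of their member stop centroids.
    """
    clusters: list[LocationCluster] = []
    for i, stop in enumerate(stops):
        for c in clusters:
            if haversine(c.lat, c.lon, stop.centroid_lat, stop.centroid_lon) <= radius_m:
                w_old = c.total_dwell_s
                w_new = max(stop.duration_s, 1e-9)
                w = w_old + w_new
                c.lat = (c.lat * w_old + stop.centroid_lat * w_new) / w
                c.lon = (c.lon * w_old + stop.centroid_lon * w_new) / w
                c.member_stop_ids.append(i)
                c.total_dwell_s += stop.duration_s
                break
        else:
            clusters.append(LocationCluster(
                location_id=len(clusters),
                lat=stop.centroid_lat, lon=stop.centroid_lon,
                member_stop_ids=[i], total_dwell_s=stop.duration_s))
    return clusters


def stop_cluster_ids(clusters: Sequence[LocationCluster], n_stops: int) -> np.ndarray:
    """Per-stop cluster id array derived from cluster membership lists."""
    ids = np.full(n_stops, -1, dtype=int)
    for c in clusters:
        for i in c.member_stop_ids:
            ids[i] = c.location_id
    return ids


def _night_dwell(stop: StopInterval, tz: str, night: tuple[int, int]) -> float:
    """Seconds of a stop overlapping the nightly [night0, night1) local window."""
    start = stop.start.tz_convert(tz)
    end = stop.end.tz_convert(tz)
    total = 0.0
    day = start.normalize()
    while day <= end.normalize():
        w0 = day + pd.Timedelta(hours=night[0])
        w1 = day + pd.Timedelta(hours=night[1])
        total += max(0.0, (min(end, w1) - max(start, w0)).total_seconds())
        day += pd.Timedelta(days=1)
    return total


def detect_home(clusters: Sequence[LocationCluster], stops: Sequence[StopInterval],
                config: FeatureConfig | None = None) -> Optional[LocationCluster]:
    """Pick the home location: the cluster with the most night-time dwell.

    Night is 00:00-06:00 local by default; ties break on total dwell.  With
    no night-time dwell anywhere the maximum total dwell wins (logged).
    Configured ``home_coords`` override everything: the nearest cluster
    within 100 m is home regardless of dwell.
    """
    config = config or FeatureConfig()
    if not clusters:
        return None
    if config.home_coords is not None:
        hlat, hlon = config.home_coords
        d = [haversine(c.lat, c.lon, hlat, hlon) for c in clusters]
        best = int(np.argmin(d))
        if d[best] <= 100.0:
            return clusters[best]
        logger.warning("configured home coordinates match no cluster within 100 m")
        return None
    night = np.array([
        sum(_night_dwell(stops[i], config.tz, config.night_hours)
            for i in c.member_stop_ids)
        for c in clusters])
    total = np.array([c.total_dwell_s for c in clusters])
    if night.max() <= 0:
        logger.warning("no night-time dwell found; falling back to max total dwell")
        return clusters[int(np.argmax(total))]
    best = np.flatnonzero(night == night.max())
    return clusters[int(best[np.argmax(total[best])])]


# ---------------------------------------------------------------------------
# geometry


def convex_hull_metrics(lats, lons, projection: LocalProjection | None = None):
    """Convex hull of a point set: (perimeter m, area m2, compactness, polygon).

    Compactness is Polsby-Popper, 4*pi*A / P^2, in (0, 1] with 1 for a
    circle.  Fewer than 3 distinct non-collinear points yield area 0 and
    NaN compactness (polygon None).
    """
    lats = np.asarray(lats, dtype=float)
    lons = np.asarray(lons, dtype=float)
    if len(lats) == 0:
        return np.nan, 0.0, np.nan, None
    proj = projection or LocalProjection.for_points(lats, lons)
    x, y = proj.forward(lats, lons)
    hull = MultiPoint(np.column_stack([x, y])).convex_hull
    # projection round-off can make collinear inputs micro-noncollinear
    if hull.geom_type != "Polygon" or hull.area < 1e-6:
        return np.nan, 0.0, np.nan, None
    perimeter = hull.exterior.length
    area = hull.area
    return float(perimeter), float(area), float(4 * np.pi * area / perimeter ** 2), hull


def standard_ellipse_area(lats, lons, projection: LocalProjection | None = None) -> float:
    """Area of the smallest covariance-shaped ellipse containing the inliers.

    Location and scatter come from the minimum covariance determinant
    estimator (robust to GPS outliers); the ellipse is scaled to the
    largest Mahalanobis distance among the estimator's support points, so
    its area is pi * s^2 * sqrt(det Sigma).  Collinear or tiny point sets
    give 0.
    """
    lats = np.asarray(lats, dtype=float)
    lons = np.asarray(lons, dtype=float)
    if len(lats) < 3:
        return 0.0
    proj = projection or LocalProjection.for_points(lats, lons)
    x, y = proj.forward(lats, lons)
    xy = np.column_stack([x, y])
    loc = xy.mean(axis=0)
    cov = np.cov(xy, rowvar=False, ddof=0)
    support = np.ones(len(xy), dtype=bool)
    if len(xy) >= 10:
        from sklearn.covariance import MinCovDet

        try:
            mcd = MinCovDet(random_state=0).fit(xy)
            loc, cov, support = mcd.location_, mcd.covariance_, mcd.support_
        except ValueError:
            pass  # degenerate scatter; the empirical fallback handles it below
    eig = np.linalg.eigvalsh(cov)
    # scatter thinner than a millimetre in some direction: no 2-D extent
    if eig.min() < 1e-6 or not np.all(np.isfinite(eig)):
        return 0.0
    det = float(np.prod(eig))
    inv = np.linalg.inv(cov)
    diff = xy[support] - loc
    s2 = float(np.max(np.einsum("ij,jk,ik->i", diff, inv, diff)))
    return float(np.pi * s2 * np.sqrt(det))


def daily_path_area(trip_paths: Sequence[pd.DataFrame], projection: LocalProjection,
                    buffer_m: float = 200.0) -> float:
    """Union area of all trip polylines buffered by ``buffer_m`` meters.

    Each trip's fixes become a LineString (a Point for single-fix trips),
    buffered with round caps and dissolved into one polygon.
    """
    shapes = []
    for path in trip_paths:
        if len(path) == 0:
            continue
        x, y = projection.forward(path["lat"].to_numpy(), path["lon"].to_numpy())
        coords = np.column_stack([x, y])
        geom = Point(coords[0]) if len(coords) == 1 else LineString(coords)
        shapes.append(geom.buffer(buffer_m))
    if not shapes:
        return 0.0
    return float(unary_union(shapes).area)


def revisited_life_space(daily_hulls: Mapping) -> tuple[dict, float]:
    """Share of each day's hull overlapped by the union of other days' hulls.

    Returns ({day: percent or NaN}, mean percent over days with valid
    hulls).  Days whose hull is missing or zero-area get NaN.
    """
    days = list(daily_hulls)
    pct: dict = {}
    for d in days:
        hull = daily_hulls[d]
        if hull is None or hull.area == 0:
            pct[d] = np.nan
            continue
        others = [daily_hulls[e] for e in days if e != d and daily_hulls[e] is not None]
        if not others:
            pct[d] = np.nan
            continue
        overlap = hull.intersection(unary_union(others)).area
        pct[d] = 100.0 * overlap / hull.area
    valid = [v for v in pct.values() if np.isfinite(v)]
    return pct, float(np.mean(valid)) if valid else np.nan


# ---------------------------------------------------------------------------
# per-trip / per-distribution variables


def mode_split(trip: TripInterval, threshold_kmh: float = 20.0) -> str:
    """Classify a trip as foot/bike or vehicle by its median leg speed.

    Vehicle iff median speed strictly exceeds ``threshold_kmh``; ties and
    degenerate single-fix trips fall to foot/bike.
    """
    if not np.isfinite(trip.median_speed_kmh):
        logger.warning("mode_split: trip at %s has no measurable speed", trip.start)
        return FOOT_BIKE
    return VEHICLE if trip.median_speed_kmh > threshold_kmh else FOOT_BIKE


def location_entropy(dwell_by_cluster: Mapping) -> float:
    """Shannon entropy (nats) of the dwell-time distribution over locations.

    0 for a single location; ln(k) for k equally-dwelled locations.  An
    empty or zero-dwell map has no defined distribution -> NaN.
    """
    dwells = np.array([v for v in dwell_by_cluster.values() if v > 0], dtype=float)
    if dwells.size == 0 or dwells.sum() <= 0:
        return np.nan
    return float(_shannon_entropy(dwells))


def trip_endpoint_keys(trips: Sequence[TripInterval], stops: Sequence[StopInterval],
                       cluster_ids: np.ndarray) -> list[Optional[tuple[int, int]]]:
    """Unordered (origin, destination) location pair per trip.

    Origin is the cluster of the stop immediately preceding the trip,
    destination that of the stop immediately following; trips at the study
    edge (no adjacent stop on one side) get None.
    """
    events = ([("s", k, s.start, s.end) for k, s in enumerate(stops)]
              + [("t", k, t.start, t.end) for k, t in enumerate(trips)])
    events.sort(key=lambda e: (e[2], e[3]))
    keys: list[Optional[tuple[int, int]]] = [None] * len(trips)
    for j, ev in enumerate(events):
        if ev[0] != "t":
            continue
        prev_stop = next((e for e in reversed(events[:j]) if e[0] == "s"), None)
        next_stop = next((e for e in events[j + 1:] if e[0] == "s"), None)
        if prev_stop is None or next_stop is None:
            continue
        o = int(cluster_ids[prev_stop[1]])
        d = int(cluster_ids[next_stop[1]])
        keys[ev[1]] = (min(o, d), max(o, d))
    return keys


def revisited_paths_pct(keys: Sequence[Optional[tuple[int, int]]]) -> float:
    """Percentage of trips whose endpoint pair occurs at least twice.

    Trips without both endpoints (None keys) are excluded from numerator
    and denominator.
    """
    present = [k for k in keys if k is not None]
    if not present:
        return np.nan
    counts = pd.Series(present).value_counts()
    revisited = sum(1 for k in present if counts[k] >= 2)
    return 100.0 * revisited / len(present)


# ---------------------------------------------------------------------------
# daily orchestration


def _clip_seconds(start: pd.Timestamp, end: pd.Timestamp,
                  d0: pd.Timestamp, d1: pd.Timestamp) -> float:
    return max(0.0, (min(end, d1) - max(start, d0)).total_seconds())


def compute_daily_features(gps: pd.DataFrame, stops: Sequence[StopInterval],
                           trips: Sequence[TripInterval],
                           config: FeatureConfig | None = None) -> pd.DataFrame:
    """One row per study day with every mobility variable.

    Day boundaries fall at local midnight of ``config.tz``.  Intervals
    spanning midnight contribute the clipped part of their duration to each
    day.  Days without any GPS data yield an all-missing row.
    """
    config = config or FeatureConfig()
    if gps.empty:
        return pd.DataFrame(columns=DAILY_COLUMNS)
    local = gps["timestamp"].dt.tz_convert(config.tz)
    dates = pd.date_range(local.min().normalize(), local.max().normalize(), freq="D")

    clusters = cluster_locations(stops, config.cluster_radius_m)
    cids = stop_cluster_ids(clusters, len(stops))
    home = detect_home(clusters, stops, config)
    home_id = home.location_id if home is not None else None
    keys = trip_endpoint_keys(trips, stops, cids)
    key_counts = pd.Series([k for k in keys if k is not None]).value_counts()

    projection = LocalProjection.for_points(gps["lat"].to_numpy(), gps["lon"].to_numpy())
    rows, hulls = [], {}
    for day in dates:
        d0 = day.tz_localize(config.tz) if day.tzinfo is None else day
        d1 = d0 + pd.Timedelta(days=1)
        day_gps = gps[(local >= d0) & (local < d1)]
        row: dict = {"date": d0.date()}
        if day_gps.empty:
            hulls[d0.date()] = None
            rows.append(row)
            continue

        if home is not None:
            dist = haversine(day_gps["lat"].to_numpy(), day_gps["lon"].to_numpy(),
                             home.lat, home.lon)
            dist = np.atleast_1d(dist)
            row["max_distance_from_home_m"] = float(dist.max())
            row["avg_distance_from_home_m"] = float(dist.mean())

        perim, area, comp, hull = convex_hull_metrics(
            day_gps["lat"].to_numpy(), day_gps["lon"].to_numpy(), projection)
        hulls[d0.date()] = hull
        row.update(hull_perimeter_m=perim, hull_area_m2=area, hull_compactness=comp)
        row["ellipse_area_m2"] = standard_ellipse_area(
            day_gps["lat"].to_numpy(), day_gps["lon"].to_numpy(), projection)

        day_stops = [(k, s, _clip_seconds(s.start, s.end, d0, d1))
                     for k, s in enumerate(stops)]
        day_stops = [(k, s, sec) for k, s, sec in day_stops if sec > 0]
        day_trips = [(k, t, _clip_seconds(t.start, t.end, d0, d1))
                     for k, t in enumerate(trips)]
        day_trips = [(k, t, sec) for k, t, sec in day_trips if sec > 0]

        row["n_locations"] = len(day_stops)
        row["n_unique_locations"] = len({cids[k] for k, _, _ in day_stops})
        row["n_revisited_locations"] = sum(
            1 for k, _, _ in day_stops if clusters[cids[k]].visit_count >= 2)

        at_home = sum(sec for k, _, sec in day_stops if cids[k] == home_id)
        away_stops = sum(sec for k, _, sec in day_stops if cids[k] != home_id)
        trip_time = sum(sec for _, _, sec in day_trips)
        row["time_at_home_s"] = at_home
        row["time_out_of_home_s"] = away_stops + trip_time

        foot = veh = 0.0
        for _, t, sec in day_trips:
            if mode_split(t, config.mode_threshold_kmh) == VEHICLE:
                veh += sec
            else:
                foot += sec
        row["time_foot_bike_s"] = foot
        row["time_vehicle_s"] = veh

        starts = [t.start.tz_convert(config.tz) for _, t, _ in day_trips
                  if d0 <= t.start.tz_convert(config.tz) < d1]
        row["first_move_time"] = (min(starts).strftime("%H:%M:%S") if starts else None)
        bin_counts = {name: sum(1 for s in starts if lo <= s.hour < hi)
                      for name, (lo, hi) in DAY_BINS.items()}
        row["time_most_moved"] = (max(bin_counts, key=lambda b: bin_counts[b])
                                  if any(bin_counts.values()) else None)

        dwell: dict[int, float] = {}
        for k, _, sec in day_stops:
            dwell[int(cids[k])] = dwell.get(int(cids[k]), 0.0) + sec
        row["location_entropy"] = location_entropy(dwell)

        day_paths = []
        for k, t, _ in day_trips:
            tloc = t.path["timestamp"].dt.tz_convert(config.tz)
            day_paths.append(t.path[(tloc >= d0) & (tloc < d1)])
        row["daily_path_area_m2"] = daily_path_area(day_paths, projection,
                                                    config.path_buffer_m)

        day_keys = [keys[k] for k, t, _ in day_trips if keys[k] is not None]
        if day_keys:
            row["revisited_paths_pct"] = 100.0 * sum(
                1 for k in day_keys if key_counts[k] >= 2) / len(day_keys)
        rows.append(row)

    pct, _avg = revisited_life_space(hulls)
    for row in rows:
        if "hull_area_m2" in row:
            row["daily_revisited_life_space_pct"] = pct.get(row["date"], np.nan)
    return pd.DataFrame(rows, columns=DAILY_COLUMNS)
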