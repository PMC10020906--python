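"""The Stop & Go classifier: per-sample stop/trip labels and interval aggregation.

A *stop* is a period of more than ``min_stop_duration_s`` (default 5 min)
spent within a ``stop_radius_m`` (default 100 m) area; a *trip* is any
period of movement between stops.  Classification proceeds in three stages:

1. **Run detection** — a greedy scan groups consecutive fixes into runs:
   a fix joins the current run while it lies within ``stop_radius_m`` of
   the run's running centroid, otherwise it founds a new run.  Runs whose
   time span exceeds ``min_stop_duration_s`` are stop candidates.
2. **Boundary refinement** — the edges of a candidate run absorb the slow
   approach/departure part of the adjacent trips (anything inside the
   radius joins the run).  Edge samples whose distance to the run centroid
   exceeds 3x the run's robust radial scatter (median distance / 1.177,
   the median of a 2-D Gaussian radius) are returned to the trip class.
3. **Motion fusion** (optional) — the accelerometer motion score separates
   physical stillness from movement where GPS alone is ambiguous:
   a candidate stop whose median motion score exceeds the threshold is
   demoted to trip (movement within a small area, e.g. slow traffic), and
   a trip gap between two stops with near-identical centroids whose median
   motion score is below the threshold is relabeled stop — this suppresses
   *fragmented stops*, single true dwells split by GPS noise excursions.

The motion threshold defaults to Otsu's method on the epoch-score
distribution, which finds the split between the at-rest and in-motion
modes; a class-separation guard (mean above / mean below >= 2) skips motion
fusion entirely when the two modes are not distinguishable (e.g. a
recording with no movement at all).  An explicitly configured threshold is
always honoured.

Recording gaps longer than ``session_gap_s`` (default 30 min — phone off or
charging) split the data into sessions; no interval ever spans a session
boundary and gap time belongs to no interval.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .geo import haversine
from .preprocess import attach_motion, deduplicate, motion_score

STOP = "stop"
TRIP = "trip"


@dataclass
class ClassifierParams:
    """Tunable parameters of the Stop & Go classifier.

    min_stop_duration_s : float
        A run must span strictly more than this to be a stop (">5 minutes":
        a dwell of exactly 300 s is a trip).
    stop_radius_m : float
        Spatial radius of a stop; also the centroid-proximity bound used
        when merging neighbouring stops.
    merge_gap_s : float
        Consecutive stops separated by less than this, with centroids
        within ``stop_radius_m``, are merged into one stop.
    motion_threshold : float or None
        Motion-score units; None derives the threshold from the data
        (Otsu split of the epoch-score distribution).
    use_motion : bool
        Disable to reproduce the purely spatial classifier.
    session_gap_s : float
        Recording gaps longer than this split the interval tiling.
    trim_k : float
        Boundary-refinement multiple of the robust radial scatter.
    """

    min_stop_duration_s: float = 300.0
    stop_radius_m: float = 100.0
    merge_gap_s: float = 120.0
    motion_threshold: Optional[float] = None
    use_motion: bool = True
    session_gap_s: float = 1800.0
    motion_epoch_s: float = 30.0
    trim_k: float = 3.0

    def __post_init__(self):
        if self.min_stop_duration_s <= 0:
            raise ValueError("min_stop_duration_s must be > 0")
        if self.stop_radius_m <= 0:
            raise ValueError("stop_radius_m must be > 0")
        if self.merge_gap_s < 0:
            raise ValueError("merge_gap_s must be >= 0")


@dataclass
class StopInterval:
    """A detected dwell: contiguous samples at one place for > 5 minutes."""

    start: pd.Timestamp
    end: pd.Timestamp
    centroid_lat: float
    centroid_lon: float
    duration_s: float
    member_count: int
    first_idx: int
    last_idx: int


@dataclass
class TripInterval:
    """A detected period of movement between two stops."""

    start: pd.Timestamp
    end: pd.Timestamp
    path: pd.DataFrame = field(repr=False)
    length_m: float
    median_speed_kmh: float
    first_idx: int
    last_idx: int


# ---------------------------------------------------------------------------
# per-sample classification


class _Run:
    """A maximal run of consecutive fixes within stop_radius of its centroid."""

    __slots__ = ("i0", "i1", "sum_lat", "sum_lon", "n", "is_stop")

    def __init__(self, i: int, lat: float, lon: float):
        self.i0 = i
        self.i1 = i
        self.sum_lat = lat
        self.sum_lon = lon
        self.n = 1
        self.is_stop = False

    @property
    def lat(self) -> float:
        return self.sum_lat / self.n

    @property
    def lon(self) -> float:
        return self.sum_lon / self.n

    def add(self, i: int, lat: float, lon: float) -> None:
        self.i1 = i
        self.sum_lat += lat
        self.sum_lon += lon
        self.n += 1


def _detect_runs(lat: np.ndarray, lon: np.ndarray, radius_m: float) -> list[_Run]:
    runs = [_Run(0, lat[0], lon[0])]
    for i in range(1, len(lat)):
        run = runs[-1]
        if haversine(run.lat, run.lon, lat[i], lon[i]) <= radius_m:
            run.add(i, lat[i], lon[i])
        else:
            runs.append(_Run(i, lat[i], lon[i]))
    return runs


def _trim_run(run: _Run, lat: np.ndarray, lon: np.ndarray, trim_k: float) -> None:
    """Expel approach/departure fixes from the edges of a candidate stop run.

    Edges are trimmed while their distance to the run centroid strictly
    exceeds trim_k times the robust radial scatter (median distance to the
    centroid, rescaled by the median of a 2-D Gaussian radius).  Trimming
    iterates to a fixpoint: slow approaches can hold many in-radius fixes
    that bias both the centroid and the scatter upward, and each trim round
    tightens both.  For a noise-free dwell the scatter converges to 0 and
    every approach/departure fix is expelled.
    """
    for _ in range(30):
        idx = np.arange(run.i0, run.i1 + 1)
        d = np.atleast_1d(haversine(run.lat, run.lon, lat[idx], lon[idx]))
        thresh = trim_k * float(np.median(d)) / 1.177
        lo, hi = 0, len(idx) - 1
        while lo <= hi and d[lo] > thresh:
            lo += 1
        while hi >= lo and d[hi] > thresh:
            hi -= 1
        if lo == 0 and hi == len(idx) - 1:
            return
        keep = idx[lo:hi + 1]
        run.i0 = int(keep[0])
        run.i1 = int(keep[-1])
        run.sum_lat = float(np.sum(lat[keep]))
        run.sum_lon = float(np.sum(lon[keep]))
        run.n = len(keep)


def derive_motion_threshold(scores: np.ndarray) -> Optional[float]:
    """Otsu split of the motion-score distribution, or None if the
    at-rest / in-motion modes are not separable (mean ratio < 2)."""
    scores = np.asarray(scores, dtype=float)
    scores = scores[np.isfinite(scores)]
    if len(scores) < 2 or np.ptp(scores) == 0:
        return None
    from skimage.filters import threshold_otsu

    t = float(threshold_otsu(scores))
    below, above = scores[scores <= t], scores[scores > t]
    if len(below) == 0 or len(above) == 0:
        return None
    mu0, mu1 = float(np.mean(below)), float(np.mean(above))
    if mu0 > 0 and mu1 / mu0 < 2.0:
        return None
    return t


def _session_slices(t_ns: np.ndarray, session_gap_s: float) -> list[slice]:
    if len(t_ns) == 0:
        return []
    breaks = np.flatnonzero(np.diff(t_ns) > session_gap_s * 1e9) + 1
    bounds = [0, *breaks.tolist(), len(t_ns)]
    return [slice(bounds[k], bounds[k + 1]) for k in range(len(bounds) - 1)]


def classify_samples(gps: pd.DataFrame, params: ClassifierParams | None = None) -> np.ndarray:
    """Label every GPS sample ``'stop'`` or ``'trip'``.

    Input must be time-sorted and deduplicated; a ``motion`` column (from
    :func:`mobitrace.preprocess.attach_motion`) enables motion fusion when
    ``params.use_motion``.  Missing motion values never flip a label, so a
    motion-free input reproduces ``use_motion=False`` exactly.
    """
    params = params or ClassifierParams()
    n = len(gps)
    if n == 0:
        return np.empty(0, dtype="<U4")
    lat = gps["lat"].to_numpy(dtype=float)
    lon = gps["lon"].to_numpy(dtype=float)
    t_ns = gps["timestamp"].astype("int64").to_numpy()
    motion = (gps["motion"].to_numpy(dtype=float)
              if params.use_motion and "motion" in gps.columns
              else np.full(n, np.nan))
    if n == 1:
        return np.array([STOP], dtype="<U4")

    threshold = params.motion_threshold
    if params.use_motion and threshold is None:
        threshold = derive_motion_threshold(motion)
    fuse = params.use_motion and threshold is not None and np.isfinite(motion).any()

    labels = np.full(n, TRIP, dtype="<U4")
    for sl in _session_slices(t_ns, params.session_gap_s):
        s_lat, s_lon, s_t = lat[sl], lon[sl], t_ns[sl]
        s_motion = motion[sl]
        runs = _detect_runs(s_lat, s_lon, params.stop_radius_m)
        for run in runs:
            span_s = (s_t[run.i1] - s_t[run.i0]) / 1e9
            if span_s > params.min_stop_duration_s:
                _trim_run(run, s_lat, s_lon, params.trim_k)
                span_s = (s_t[run.i1] - s_t[run.i0]) / 1e9
                run.is_stop = span_s > params.min_stop_duration_s
        if fuse:
            _motion_fusion(runs, s_lat, s_lon, s_t, s_motion, threshold, params)
        base = sl.start
        for run in runs:
            if run.is_stop:
                labels[base + run.i0: base + run.i1 + 1] = STOP
    return labels


def _median_present(values: np.ndarray) -> float:
    present = values[np.isfinite(values)]
    return float(np.median(present)) if len(present) else np.nan


def _motion_fusion(runs: list[_Run], lat, lon, t_ns, motion, threshold: float,
                   params: ClassifierParams) -> None:
    # demotion: sustained physical motion inside a spatially-stationary run
    for run in runs:
        if run.is_stop:
            med = _median_present(motion[run.i0: run.i1 + 1])
            if np.isfinite(med) and med > threshold:
                run.is_stop = False
    # fragment suppression: bridge trip gaps between co-located still stops
    stop_runs = [r for r in runs if r.is_stop]
    k = 0
    while k + 1 < len(stop_runs):
        a, b = stop_runs[k], stop_runs[k + 1]
        gap = motion[a.i1 + 1: b.i0]
        med = _median_present(gap)
        close = haversine(a.lat, a.lon, b.lat, b.lon) <= params.stop_radius_m
        if close and len(gap) and np.isfinite(med) and med <= threshold:
            # absorb the gap and the right-hand run into the left-hand run
            for i in range(a.i1 + 1, b.i1 + 1):
                a.add(i, lat[i], lon[i])
            for run in runs:
                if a.i0 < run.i0 <= b.i0:
                    run.is_stop = False  # superseded; a covers its samples
            a.is_stop = True
            stop_runs.pop(k + 1)
        else:
            k += 1
    # re-expand: mark absorbed samples as stop via the surviving runs
    for r in stop_runs:
        r.is_stop = True


# ---------------------------------------------------------------------------
# interval aggregation


def aggregate_intervals(labels: np.ndarray, gps: pd.DataFrame,
                        params: ClassifierParams | None = None,
                        ) -> tuple[list[StopInterval], list[TripInterval]]:
    """Aggregate per-sample labels into stop and trip intervals.

    Within each recording session stops and trips tile the covered time
    exactly: interval k ends where interval k+1 starts (the first sample
    of the next run), the last interval ends at its own last sample.
    Sub-minimum stop runs are relabeled trip; neighbouring stops separated
    by less than ``merge_gap_s`` with centroids within ``stop_radius_m``
    are merged (absorbing the samples between them).
    """
    params = params or ClassifierParams()
    if len(labels) != len(gps):
        raise ValueError(f"labels ({len(labels)}) and gps ({len(gps)}) length mismatch")
    if len(gps) == 0:
        return [], []
    lat = gps["lat"].to_numpy(dtype=float)
    lon = gps["lon"].to_numpy(dtype=float)
    t_ns = gps["timestamp"].astype("int64").to_numpy()
    ts = gps["timestamp"]

    stops: list[StopInterval] = []
    trips: list[TripInterval] = []
    for sl in _session_slices(t_ns, params.session_gap_s):
        runs = _label_runs(labels, sl)
        runs = _demote_short_stops(runs, t_ns, params)
        runs = _merge_nearby_stops(runs, lat, lon, t_ns, params)
        for k, (i0, i1, lab) in enumerate(runs):
            start = ts.iloc[i0]
            end = ts.iloc[runs[k + 1][0]] if k + 1 < len(runs) else ts.iloc[i1]
            if lab == STOP:
                stops.append(StopInterval(
                    start=start, end=end,
                    centroid_lat=float(np.mean(lat[i0:i1 + 1])),
                    centroid_lon=float(np.mean(lon[i0:i1 + 1])),
                    duration_s=float((end - start).total_seconds()),
                    member_count=i1 - i0 + 1, first_idx=i0, last_idx=i1))
            else:
                path = gps.iloc[i0:i1 + 1]
                legs = haversine(lat[i0:i1], lon[i0:i1], lat[i0 + 1:i1 + 1], lon[i0 + 1:i1 + 1])
                legs = np.atleast_1d(legs)
                dt = np.diff(t_ns[i0:i1 + 1]) / 1e9
                valid = dt > 0
                speeds = 3.6 * legs[valid] / dt[valid]
                trips.append(TripInterval(
                    start=start, end=end, path=path,
                    length_m=float(np.sum(legs)),
                    median_speed_kmh=float(np.median(speeds)) if len(speeds) else np.nan,
                    first_idx=i0, last_idx=i1))
    return stops, trips


def _label_runs(labels: np.ndarray, sl: slice) -> list[tuple[int, int, str]]:
    """Maximal constant-label runs as (first_idx, last_idx, label), global indices."""
    idx = np.arange(sl.start, sl.stop)
    lab = labels[sl]
    breaks = np.flatnonzero(lab[1:] != lab[:-1]) + 1
    bounds = [0, *breaks.tolist(), len(lab)]
    return [(int(idx[bounds[k]]), int(idx[bounds[k + 1] - 1]), str(lab[bounds[k]]))
            for k in range(len(bounds) - 1)]


def _demote_short_stops(runs, t_ns, params) -> list[tuple[int, int, str]]:
    out: list[tuple[int, int, str]] = []
    for i0, i1, lab in runs:
        if lab == STOP and (t_ns[i1] - t_ns[i0]) / 1e9 <= params.min_stop_duration_s:
            lab = TRIP
        if out and out[-1][2] == lab:
            out[-1] = (out[-1][0], i1, lab)
        else:
            out.append((i0, i1, lab))
    return out


def _merge_nearby_stops(runs, lat, lon, t_ns, params) -> list[tuple[int, int, str]]:
    """Merge stop-trip-stop triples with a short gap and co-located centroids."""
    changed = True
    while changed:
        changed = False
        for k in range(len(runs) - 2):
            (a0, a1, la), (g0, g1, lg), (b0, b1, lb) = runs[k], runs[k + 1], runs[k + 2]
            if la != STOP or lg != TRIP or lb != STOP:
                continue
            gap_s = (t_ns[b0] - t_ns[a1]) / 1e9
            d = haversine(float(np.mean(lat[a0:a1 + 1])), float(np.mean(lon[a0:a1 + 1])),
                          float(np.mean(lat[b0:b1 + 1])), float(np.mean(lon[b0:b1 + 1])))
            if gap_s < params.merge_gap_s and d <= params.stop_radius_m:
                runs[k:k + 3] = [(a0, b1, STOP)]
                changed = True
                break
    return runs


# ---------------------------------------------------------------------------
# end-to-end


def run_stop_go(gps: pd.DataFrame, accel: pd.DataFrame | None = None,
                params: ClassifierParams | None = None,
                ) -> tuple[list[StopInterval], list[TripInterval], pd.DataFrame]:
    """Full classification: dedup -> motion score -> classify -> aggregate.

    Returns (stops, trips, labeled GPS frame).  With ``use_motion=False``
    or no accelerometer data, the accelerometer input is ignored entirely.
    """
    params = params or ClassifierParams()
    gps = deduplicate(gps)
    if params.use_motion and accel is not None and len(accel):
        series = motion_score(accel, params.motion_epoch_s)
    else:
        series = None
    annotated = attach_motion(gps, series) if series is not None else gps.assign(motion=np.nan)
    labels = classify_samples(annotated, params)
    stops, trips = aggregate_intervals(labels, annotated, params)
    labeled = annotated.assign(label=labels)
    return stops, trips, labeled


def stops_to_frame(stops: list[StopInterval]) -> pd.DataFrame:
    """Stop intervals as a DataFrame (stable column order for CSV output)."""
    return pd.DataFrame([{
        "start": s.start, "end": s.end,
        "centroid_lat": s.centroid_lat, "centroid_lon": s.centroid_lon,
        "duration_s": s.duration_s, "member_count": s.member_count,
    } for s in stops], columns=["start", "end", "centroid_lat", "centroid_lon",
                                "duration_s", "member_count"])


def trips_to_frame(trips: list[TripInterval]) -> pd.DataFrame:
    """Trip intervals as a DataFrame (paths omitted)."""
    return pd.DataFrame([{
        "start": t.start, "end": t.end, "length_m": t.length_m,
        "median_speed_kmh": t.median_speed_kmh,
    } for t in trips], columns=["start", "end", "length_m", "median_speed_kmh"])
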