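"""Seeded simulator of a GPS + accelerometer + diary field study.

Emulates the recording conditions of a smartphone mobility study: a
participant alternates dwells at a small set of places (one of them home)
with trips at pedestrian/bicycle or vehicle speeds; the phone logs a GPS
fix every 10 s (isotropic Gaussian position noise, occasional dropout) and
1 Hz 3-axis accelerometry whose variance differs between carrying-while-
moving and at-rest states.  Every dwell longer than 5 minutes is written to
the ground-truth diary, exactly as a participant logging stays would.

The movement model is a piecewise-constant-speed straight line between
places — enough to exercise every downstream metric without a road
network.  All randomness flows from one ``numpy`` Generator seeded by
``SimConfig.seed``, so identical configs give bit-identical studies.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .geo import LocalProjection, haversine
from .stopgo import STOP, TRIP

GRAVITY = 9.81


@dataclass
class LocationSpec:
    """A place the simulated participant can visit."""

    name: str
    lat: float
    lon: float
    is_home: bool = False
    dwell_mean_s: float = 3600.0
    dwell_sd_s: float = 900.0


def default_locations(center_lat: float = 52.52, center_lon: float = 13.405,
                      ) -> list[LocationSpec]:
    """Home plus five places 0.4-5 km away, typical of an urban daily round."""
    proj = LocalProjection(center_lat, center_lon)
    places = [
        ("home", 0.0, 0.0, True, 4 * 3600.0, 3600.0),
        ("supermarket", 400.0, 250.0, False, 1500.0, 400.0),
        ("park", -700.0, 900.0, False, 2700.0, 800.0),
        ("friend", 1800.0, -1200.0, False, 5400.0, 1500.0),
        ("doctor", -2500.0, -1800.0, False, 2400.0, 600.0),
        ("work", 4200.0, 2600.0, False, 3 * 3600.0, 1800.0),
    ]
    out = []
    for name, x, y, is_home, mean, sd in places:
        lat, lon = proj.inverse(x, y)
        out.append(LocationSpec(name, float(lat), float(lon), is_home, mean, sd))
    return out


@dataclass
class SimConfig:
    """Study conditions for :func:`simulate_study`.

    Defaults mirror the recording setup of a smartphone field study:
    10-second GPS interval, 1 Hz accelerometry, ~10 m GPS position noise,
    and a diary rate of roughly 5-6 stops per day.
    """

    seed: int = 0
    n_days: int = 7
    locations: list[LocationSpec] = field(default_factory=default_locations)
    excursions_per_day: float = 2.3
    short_dwell_prob: float = 0.15
    p_vehicle: float = 0.35
    foot_bike_speed_kmh: tuple[float, float] = (3.0, 16.0)
    vehicle_speed_kmh: tuple[float, float] = (25.0, 60.0)
    gps_noise_sigma_m: float = 10.0
    gps_interval_s: float = 10.0
    accel_rate_hz: float = 1.0
    rest_accel_sigma: float = 0.05
    move_accel_sigma: float = 0.8
    dropout_prob: float = 0.02
    start: str = "2022-03-01"
    tz: str = "UTC"

    def __post_init__(self):
        if self.gps_interval_s <= 0 or self.accel_rate_hz <= 0:
            raise ValueError("sampling rates must be positive")
        if self.gps_noise_sigma_m < 0 or self.rest_accel_sigma <= 0 \
                or self.move_accel_sigma <= 0:
            raise ValueError("noise sigmas must be positive")
        if not 0 <= self.dropout_prob <= 1 or not 0 <= self.p_vehicle <= 1 \
                or not 0 <= self.short_dwell_prob <= 1:
            raise ValueError("probabilities must lie in [0, 1]")
        if not any(l.is_home for l in self.locations):
            raise ValueError("one location must be flagged home")


@dataclass
class _Segment:
    """One schedule entry on the study timeline (seconds from study start)."""

    t0: float
    t1: float
    kind: str                    # "dwell" | "trip"
    loc: Optional[int] = None    # dwell location index
    frm: Optional[int] = None    # trip endpoints
    to: Optional[int] = None
    mode: Optional[str] = None   # "foot_bike" | "vehicle"
    speed_kmh: float = np.nan

    @property
    def duration(self) -> float:
        return self.t1 - self.t0


@dataclass
class SyntheticStudy:
    """Simulator output: sensor frames, diary ground truth and bookkeeping."""

    gps: pd.DataFrame
    accel: pd.DataFrame
    diary: pd.DataFrame
    truth_labels: np.ndarray
    truth_features: pd.DataFrame
    segments: list[_Segment]
    config: SimConfig


def _build_schedule(cfg: SimConfig, rng: np.random.Generator) -> list[_Segment]:
    """Alternating home dwells, trips and away dwells over the study days."""
    proj = LocalProjection(*_home_coords(cfg))
    xy = np.column_stack(proj.forward([l.lat for l in cfg.locations],
                                      [l.lon for l in cfg.locations]))
    home = next(i for i, l in enumerate(cfg.locations) if l.is_home)
    away = [i for i in range(len(cfg.locations)) if i != home]

    def trip_time(a: int, b: int, speed_kmh: float) -> float:
        dist = float(np.hypot(*(xy[a] - xy[b])))
        return dist / (speed_kmh / 3.6)

    max_dist = max((float(np.hypot(*(xy[home] - xy[i]))) for i in away), default=0.0)
    if max_dist / (min(cfg.foot_bike_speed_kmh) / 3.6) > 86400:
        raise ValueError("impossible schedule: slowest trip longer than a day")

    segments: list[_Segment] = []
    t = 0.0
    horizon = cfg.n_days * 86400.0
    for day in range(cfg.n_days):
        day_end = (day + 1) * 86400.0
        depart = day * 86400.0 + rng.uniform(7.5, 10.0) * 3600.0
        n_exc = int(rng.poisson(cfg.excursions_per_day))
        for _ in range(n_exc):
            dest = int(rng.choice(away))
            short = rng.random() < cfg.short_dwell_prob
            spec = cfg.locations[dest]
            if short:
                dwell = float(rng.uniform(60.0, 240.0))
            else:
                dwell = max(360.0, float(rng.normal(spec.dwell_mean_s, spec.dwell_sd_s)))
            vehicle = rng.random() < cfg.p_vehicle
            lo, hi = cfg.vehicle_speed_kmh if vehicle else cfg.foot_bike_speed_kmh
            speed_out = float(rng.uniform(lo, hi))
            # same mode both ways so a short (sub-stop) dwell folds into one trip
            speed_back = speed_out if short else float(rng.uniform(lo, hi))
            mode = "vehicle" if vehicle else "foot_bike"
            out_s = trip_time(home, dest, speed_out)
            back_s = trip_time(dest, home, speed_back)
            arrive_home = depart + out_s + dwell + back_s
            if arrive_home > day_end - 1800.0:
                break
            segments.append(_Segment(t0=depart, t1=depart + out_s, kind="trip",
                                     frm=home, to=dest, mode=mode, speed_kmh=speed_out))
            segments.append(_Segment(t0=depart + out_s, t1=depart + out_s + dwell,
                                     kind="dwell", loc=dest))
            segments.append(_Segment(t0=depart + out_s + dwell, t1=arrive_home,
                                     kind="trip", frm=dest, to=home, mode=mode,
                                     speed_kmh=speed_back))
            depart = arrive_home + rng.uniform(1800.0, 7200.0)

    # fill every uncovered span with home dwells, merging across midnight
    filled: list[_Segment] = []
    for seg in segments:
        if seg.t0 > t:
            filled.append(_Segment(t0=t, t1=seg.t0, kind="dwell", loc=home))
        filled.append(seg)
        t = seg.t1
    if t < horizon:
        filled.append(_Segment(t0=t, t1=horizon, kind="dwell", loc=home))
    return filled


def _home_coords(cfg: SimConfig) -> tuple[float, float]:
    home = next(l for l in cfg.locations if l.is_home)
    return home.lat, home.lon


def simulate_study(config: SimConfig | None = None) -> SyntheticStudy:
    """Generate a complete synthetic study (GPS, accel, diary, bookkeeping).

    Deterministic in ``config.seed``; ``n_days=0`` yields an empty study.
    """
    cfg = config or SimConfig()
    rng = np.random.default_rng(cfg.seed)
    start = pd.Timestamp(cfg.start, tz=cfg.tz).tz_convert("UTC")
    if cfg.n_days == 0:
        empty_gps = pd.DataFrame(columns=["timestamp", "lat", "lon"])
        empty_accel = pd.DataFrame(columns=["timestamp", "ax", "ay", "az"])
        empty_diary = pd.DataFrame(columns=["begin", "end", "lat", "lon", "address"])
        return SyntheticStudy(empty_gps, empty_accel, empty_diary,
                              np.empty(0, dtype="<U4"), pd.DataFrame(), [], cfg)

    segments = _build_schedule(cfg, rng)
    proj = LocalProjection(*_home_coords(cfg))
    xy = np.column_stack(proj.forward([l.lat for l in cfg.locations],
                                      [l.lon for l in cfg.locations]))

    horizon = cfg.n_days * 86400.0
    t_fix = np.arange(0.0, horizon, cfg.gps_interval_s)
    true_xy = np.empty((len(t_fix), 2))
    for seg in segments:
        m = (t_fix >= seg.t0) & (t_fix < seg.t1)
        if not m.any():
            continue
        if seg.kind == "dwell":
            true_xy[m] = xy[seg.loc]
        else:
            frac = ((t_fix[m] - seg.t0) / seg.duration)[:, None]
            true_xy[m] = xy[seg.frm] + frac * (xy[seg.to] - xy[seg.frm])

    noisy_xy = true_xy + rng.normal(0.0, cfg.gps_noise_sigma_m, true_xy.shape) \
        if cfg.gps_noise_sigma_m > 0 else true_xy.copy()
    keep = rng.random(len(t_fix)) >= cfg.dropout_prob

    # diary = every dwell longer than 5 minutes, exactly as a tester would log it
    diary_rows = [seg for seg in segments if seg.kind == "dwell" and seg.duration > 300.0]
    diary = pd.DataFrame({
        "begin": [start + pd.Timedelta(seconds=s.t0) for s in diary_rows],
        "end": [start + pd.Timedelta(seconds=s.t1) for s in diary_rows],
        "lat": [cfg.locations[s.loc].lat for s in diary_rows],
        "lon": [cfg.locations[s.loc].lon for s in diary_rows],
        "address": [cfg.locations[s.loc].name for s in diary_rows],
    })

    labels = np.full(len(t_fix), TRIP, dtype="<U4")
    for s in diary_rows:
        labels[(t_fix >= s.t0) & (t_fix <= s.t1)] = STOP

    lat, lon = proj.inverse(noisy_xy[keep, 0], noisy_xy[keep, 1])
    gps = pd.DataFrame({
        "timestamp": start + pd.to_timedelta(t_fix[keep], unit="s"),
        "lat": lat, "lon": lon,
    })

    # 1 Hz accelerometry: gravity on z plus per-axis noise, sigma by motion state
    t_acc = np.arange(0.0, horizon, 1.0 / cfg.accel_rate_hz)
    moving = np.zeros(len(t_acc), dtype=bool)
    for seg in segments:
        if seg.kind == "trip":
            moving |= (t_acc >= seg.t0) & (t_acc < seg.t1)
    sigma = np.where(moving, cfg.move_accel_sigma, cfg.rest_accel_sigma)[:, None]
    noise = rng.normal(0.0, 1.0, (len(t_acc), 3)) * sigma
    accel = pd.DataFrame({
        "timestamp": start + pd.to_timedelta(t_acc, unit="s"),
        "ax": noise[:, 0], "ay": noise[:, 1], "az": GRAVITY + noise[:, 2],
    })

    truth_features = _truth_bookkeeping(cfg, segments, diary_rows, true_xy, t_fix,
                                        xy, start)
    return SyntheticStudy(gps, accel, diary, labels[keep], truth_features,
                          segments, cfg)


def _truth_bookkeeping(cfg: SimConfig, segments: list[_Segment],
                       diary_rows: list[_Segment], true_xy: np.ndarray,
                       t_fix: np.ndarray, loc_xy: np.ndarray,
                       start: pd.Timestamp) -> pd.DataFrame:
    """Per-day ground truth for the schedule-derivable daily variables."""
    home = next(i for i, l in enumerate(cfg.locations) if l.is_home)
    visits_per_loc: dict[int, int] = {}
    for s in diary_rows:
        visits_per_loc[s.loc] = visits_per_loc.get(s.loc, 0) + 1

    dist_home = np.hypot(true_xy[:, 0] - loc_xy[home, 0],
                         true_xy[:, 1] - loc_xy[home, 1])
    rows = []
    for day in range(cfg.n_days):
        d0, d1 = day * 86400.0, (day + 1) * 86400.0

        def clip(seg: _Segment) -> float:
            return max(0.0, min(seg.t1, d1) - max(seg.t0, d0))

        day_dwells = [s for s in diary_rows if clip(s) > 0]
        day_trips = [s for s in segments if s.kind == "trip" and clip(s) > 0]
        at_home = sum(clip(s) for s in day_dwells if s.loc == home)
        dwell_by_loc: dict[int, float] = {}
        for s in day_dwells:
            dwell_by_loc[s.loc] = dwell_by_loc.get(s.loc, 0.0) + clip(s)
        p = np.array([v for v in dwell_by_loc.values() if v > 0])
        ent = float(-(p / p.sum() @ np.log(p / p.sum()))) if p.size else np.nan

        trip_starts = [s.t0 for s in day_trips if d0 <= s.t0 < d1]
        first_move = (start + pd.Timedelta(seconds=min(trip_starts))
                      ).tz_convert(cfg.tz).strftime("%H:%M:%S") if trip_starts else None
        bins = {name: sum(1 for t0 in trip_starts
                          if lo <= ((t0 % 86400.0) / 3600.0) < hi)
                for name, (lo, hi) in
                {"morning": (5, 11), "noon": (11, 17), "evening": (17, 23)}.items()}
        in_day = (t_fix >= d0) & (t_fix < d1)
        rows.append({
            "date": (start + pd.Timedelta(seconds=d0)).tz_convert(cfg.tz).date(),
            "n_locations": len(day_dwells),
            "n_unique_locations": len({s.loc for s in day_dwells}),
            "n_revisited_locations": sum(1 for s in day_dwells
                                         if visits_per_loc[s.loc] >= 2),
            "time_at_home_s": at_home,
            "time_out_of_home_s": (d1 - d0) - at_home,
            "time_foot_bike_s": sum(clip(s) for s in day_trips
                                    if s.mode == "foot_bike"),
            "time_vehicle_s": sum(clip(s) for s in day_trips if s.mode == "vehicle"),
            "first_move_time": first_move,
            "time_most_moved": (max(bins, key=lambda b: bins[b])
                                if any(bins.values()) else None),
            "location_entropy": ent,
            "max_distance_from_home_m": float(dist_home[in_day].max()),
            "avg_distance_from_home_m": float(dist_home[in_day].mean()),
        })
    return pd.DataFrame(rows)


def degrade(study: SyntheticStudy, extra_noise_sigma_m: float = 0.0,
            burst_prob: float = 0.0, burst_max_m: float = 300.0,
            seed: Optional[int] = None) -> SyntheticStudy:
    """Overlay suboptimal-reception artifacts on a study's GPS fixes.

    Adds isotropic Gaussian noise of ``extra_noise_sigma_m`` and, with
    probability ``burst_prob`` per fix, a heavy-tailed position burst of
    uniform magnitude up to ``burst_max_m`` in a random direction.  Ground
    truth (diary, labels, bookkeeping) is untouched.  With zero noise and
    zero bursts the study is returned unchanged.
    """
    if extra_noise_sigma_m == 0.0 and burst_prob == 0.0:
        return study
    rng = np.random.default_rng(study.config.seed + 1 if seed is None else seed)
    proj = LocalProjection(*_home_coords(study.config))
    x, y = proj.forward(study.gps["lat"].to_numpy(), study.gps["lon"].to_numpy())
    n = len(x)
    if extra_noise_sigma_m > 0:
        x = x + rng.normal(0.0, extra_noise_sigma_m, n)
        y = y + rng.normal(0.0, extra_noise_sigma_m, n)
    if burst_prob > 0:
        hit = rng.random(n) < burst_prob
        mag = rng.uniform(0.0, burst_max_m, n)
        ang = rng.uniform(0.0, 2 * np.pi, n)
        x = x + hit * mag * np.cos(ang)
        y = y + hit * mag * np.sin(ang)
    lat, lon = proj.inverse(x, y)
    gps = study.gps.copy()
    gps["lat"] = lat
    gps["lon"] = lon
    return replace(study, gps=gps)


def write_study_csvs(study: SyntheticStudy, dest) -> dict[str, Path]:
    """Write gps.csv / accel.csv / diary.csv in the default reader dialect."""
    dest = Path(dest)
    dest.mkdir(parents=True, exist_ok=True)
    paths = {}
    gps = study.gps.copy()
    gps["timestamp"] = gps["timestamp"].dt.strftime("%Y-%m-%dT%H:%M:%S%z")
    paths["gps"] = dest / "gps.csv"
    gps.to_csv(paths["gps"], index=False)

    accel = study.accel.rename(columns={"ax": "acc_x", "ay": "acc_y", "az": "acc_z"})
    accel["timestamp"] = accel["timestamp"].dt.strftime("%Y-%m-%dT%H:%M:%S%z")
    paths["accel"] = dest / "accel.csv"
    accel.to_csv(paths["accel"], index=False)

    diary = study.diary.copy()
    for col in ("begin", "end"):
        diary[col] = diary[col].dt.strftime("%Y-%m-%dT%H:%M:%S%z")
    paths["diary"] = dest / "diary.csv"
    diary.to_csv(paths["diary"], index=False)
    return paths
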