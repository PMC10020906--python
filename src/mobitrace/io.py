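"""Reading and writing external formats.

Raw sensor records arrive as CSV files whose column names vary between
deployments, so every reader takes a :class:`ColumnMap` with sensible
defaults.  Internally the package works with pandas DataFrames using
canonical columns:

* GPS:   ``timestamp`` (tz-aware UTC), ``lat``, ``lon``, optional ``accuracy``
* accel: ``timestamp``, ``ax``, ``ay``, ``az``
* diary: ``begin``, ``end``, ``lat``, ``lon``, optional ``address``

Timestamps are parsed as ISO-8601 strings or epoch seconds/milliseconds
(auto-detected per file) and always normalised to UTC: study phones are
shipped across time zones, so local wall-clock time is unsafe as an
internal representation.
"""

from __future__ import annotations

import logging
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

GPX_NS = "http://www.topografix.com/GPX/1/1"


class ConfigurationError(ValueError):
    """A reader was pointed at a file missing a mandatory column."""


class EmptyInputError(ValueError):
    """An input yielded zero valid records."""


@dataclass
class ColumnMap:
    """Maps a CSV dialect onto the canonical column names."""

    timestamp: str = "timestamp"
    lat: str = "lat"
    lon: str = "lon"
    accuracy: str | None = "accuracy"
    ax: str = "acc_x"
    ay: str = "acc_y"
    az: str = "acc_z"
    diary_begin: str = "begin"
    diary_end: str = "end"
    diary_address: str | None = "address"


@dataclass
class StudyWindow:
    """Per-participant study interval; closed on both ends.

    When constructed from dates (no time component) the window spans the
    whole start and end days: start 00:00:00 through end 23:59:59.999...,
    matching a day-granularity study protocol where participants begin
    one day after receiving the device.
    """

    start: pd.Timestamp
    end: pd.Timestamp

    def __post_init__(self):
        self.start = _to_utc_instant(self.start, end_of_day=False)
        self.end = _to_utc_instant(self.end, end_of_day=True)
        if self.start > self.end:
            raise ValueError(f"study window start {self.start} after end {self.end}")


def _to_utc_instant(value, end_of_day: bool) -> pd.Timestamp:
    date_only = isinstance(value, str) and len(value.strip()) == 10
    ts = pd.Timestamp(value)
    if ts.tzinfo is None:
        ts = ts.tz_localize("UTC")
    else:
        ts = ts.tz_convert("UTC")
    if date_only and end_of_day:
        ts = ts + pd.Timedelta(days=1) - pd.Timedelta(nanoseconds=1)
    return ts


def _parse_timestamps(raw: pd.Series) -> pd.Series:
    """ISO-8601 or epoch seconds/milliseconds -> tz-aware UTC datetimes.

    Unparseable entries become NaT (callers drop and count them).
    """
    numeric = pd.to_numeric(raw, errors="coerce")
    if numeric.notna().mean() > 0.5:
        # epoch: values above ~1e11 can only be milliseconds (year >5138 in s)
        unit = "ms" if numeric.abs().median() > 1e11 else "s"
        return pd.to_datetime(numeric, unit=unit, errors="coerce", utc=True)
    return pd.to_datetime(raw, errors="coerce", utc=True, format="ISO8601")


def _require(df: pd.DataFrame, names: list[str], source) -> None:
    missing = [n for n in names if n not in df.columns]
    if missing:
        raise ConfigurationError(
            f"{source}: missing mandatory column(s) {missing}; present: {list(df.columns)}")


def read_gps_records(source, column_map: ColumnMap | None = None) -> pd.DataFrame:
    """Read a GPS fix CSV into the canonical GPS frame, sorted by time.

    Rows with unparseable timestamps or out-of-range coordinates are
    skipped; the skip count is logged and attached as ``df.attrs['skipped']``.
    """
    cm = column_map or ColumnMap()
    raw = pd.read_csv(source)
    _require(raw, [cm.timestamp, cm.lat, cm.lon], source)
    df = pd.DataFrame({
        "timestamp": _parse_timestamps(raw[cm.timestamp]),
        "lat": pd.to_numeric(raw[cm.lat], errors="coerce"),
        "lon": pd.to_numeric(raw[cm.lon], errors="coerce"),
    })
    if cm.accuracy and cm.accuracy in raw.columns:
        df["accuracy"] = pd.to_numeric(raw[cm.accuracy], errors="coerce")
    ok = (df["timestamp"].notna()
          & df["lat"].between(-90.0, 90.0)
          & df["lon"].between(-180.0, 180.0))
    skipped = int((~ok).sum())
    if skipped:
        logger.warning("read_gps_records(%s): skipped %d invalid rows", source, skipped)
    df = df[ok].sort_values("timestamp", kind="stable").reset_index(drop=True)
    if df.empty:
        raise EmptyInputError(f"{source}: no valid GPS rows")
    df.attrs["skipped"] = skipped
    return df


def read_accel_records(source, column_map: ColumnMap | None = None) -> pd.DataFrame:
    """Read a 3-axis accelerometer CSV, sorted by time.

    Duplicate timestamps are retained — deduplication belongs to the
    preprocessing stage.
    """
    cm = column_map or ColumnMap()
    raw = pd.read_csv(source)
    _require(raw, [cm.timestamp, cm.ax, cm.ay, cm.az], source)
    df = pd.DataFrame({
        "timestamp": _parse_timestamps(raw[cm.timestamp]),
        "ax": pd.to_numeric(raw[cm.ax], errors="coerce"),
        "ay": pd.to_numeric(raw[cm.ay], errors="coerce"),
        "az": pd.to_numeric(raw[cm.az], errors="coerce"),
    })
    ok = df.notna().all(axis=1) & np.isfinite(df[["ax", "ay", "az"]]).all(axis=1)
    skipped = int((~ok).sum())
    if skipped:
        logger.warning("read_accel_records(%s): skipped %d invalid rows", source, skipped)
    df = df[ok].sort_values("timestamp", kind="stable").reset_index(drop=True)
    if df.empty:
        raise EmptyInputError(f"{source}: no valid accelerometer rows")
    df.attrs["skipped"] = skipped
    return df


def read_diary(source, column_map: ColumnMap | None = None) -> pd.DataFrame:
    """Read a stop diary (ground truth) CSV, sorted by begin time.

    Each record is one logged stay: begin/end instants and the location's
    coordinates.  Raises on begin >= end or on overlapping stays.
    """
    cm = column_map or ColumnMap()
    raw = pd.read_csv(source)
    _require(raw, [cm.diary_begin, cm.diary_end, cm.lat, cm.lon], source)
    df = pd.DataFrame({
        "begin": _parse_timestamps(raw[cm.diary_begin]),
        "end": _parse_timestamps(raw[cm.diary_end]),
        "lat": pd.to_numeric(raw[cm.lat], errors="coerce"),
        "lon": pd.to_numeric(raw[cm.lon], errors="coerce"),
    })
    if cm.diary_address and cm.diary_address in raw.columns:
        df["address"] = raw[cm.diary_address]
    bad = df.index[(df["begin"].isna()) | (df["end"].isna()) | (df["begin"] >= df["end"])]
    if len(bad):
        raise ValueError(f"{source}: diary row(s) {list(bad)} have begin >= end or bad times")
    df = df.sort_values("begin", kind="stable").reset_index(drop=True)
    overlap = df.index[1:][df["begin"].values[1:] < df["end"].values[:-1]]
    if len(overlap):
        raise ValueError(f"{source}: diary stops overlap at sorted row(s) {list(overlap)}")
    return df


def trim_to_study_window(df: pd.DataFrame, window: StudyWindow) -> pd.DataFrame:
    """Keep only records inside the closed study interval.

    Works on any canonical frame with a ``timestamp`` column (GPS, accel);
    order is preserved.  Empty output is allowed.
    """
    keep = (df["timestamp"] >= window.start) & (df["timestamp"] <= window.end)
    return df[keep].reset_index(drop=True)


def export_gpx(gps: pd.DataFrame, dest) -> None:
    """Write GPS fixes as a single-track GPX 1.1 document.

    Coordinates are stored at 7 decimal places (~1 cm), timestamps at
    second precision.  ``accuracy``, when present, travels in a track-point
    extension element.
    """
    if gps.empty:
        raise EmptyInputError("export_gpx: no fixes to export")
    ET.register_namespace("", GPX_NS)
    root = ET.Element(f"{{{GPX_NS}}}gpx", {"version": "1.1", "creator": "mobitrace"})
    trk = ET.SubElement(root, f"{{{GPX_NS}}}trk")
    seg = ET.SubElement(trk, f"{{{GPX_NS}}}trkseg")
    has_acc = "accuracy" in gps.columns
    for row in gps.itertuples(index=False):
        pt = ET.SubElement(seg, f"{{{GPX_NS}}}trkpt",
                           {"lat": f"{row.lat:.7f}", "lon": f"{row.lon:.7f}"})
        t = ET.SubElement(pt, f"{{{GPX_NS}}}time")
        t.text = row.timestamp.strftime("%Y-%m-%dT%H:%M:%SZ")
        if has_acc and np.isfinite(getattr(row, "accuracy", np.nan)):
            ext = ET.SubElement(pt, f"{{{GPX_NS}}}extensions")
            acc = ET.SubElement(ext, f"{{{GPX_NS}}}accuracy")
            acc.text = f"{row.accuracy:g}"
    tree = ET.ElementTree(root)
    ET.indent(tree)
    tree.write(dest, xml_declaration=True, encoding="unicode" if hasattr(dest, "write") else "utf-8")


def read_gpx(source) -> pd.DataFrame:
    """Parse a GPX 1.1 track back into the canonical GPS frame."""
    root = ET.parse(source).getroot()
    rows = []
    for pt in root.iter(f"{{{GPX_NS}}}trkpt"):
        t = pt.find(f"{{{GPX_NS}}}time")
        acc = pt.find(f"{{{GPX_NS}}}extensions/{{{GPX_NS}}}accuracy")
        rows.append({
            "timestamp": pd.Timestamp(t.text) if t is not None else pd.NaT,
            "lat": float(pt.get("lat")),
            "lon": float(pt.get("lon")),
            "accuracy": float(acc.text) if acc is not None else np.nan,
        })
    df = pd.DataFrame(rows)
    if not df.empty:
        df["timestamp"] = pd.to_datetime(df["timestamp"], utc=True)
    return df


#: column order of stops.csv — stable so outputs are byte-identical across runs
STOPS_COLUMNS = ["participant", "start", "end", "centroid_lat", "centroid_lon",
                 "duration_s", "location_id", "is_home"]


def write_results(stops: pd.DataFrame, daily: pd.DataFrame, dest,
                  participant: str = "P01") -> tuple[Path, Path]:
    """Write the two result tables: ``stops.csv`` and ``daily_features.csv``.

    Column order is fixed and missing values are written as empty fields,
    so re-running on identical input gives byte-identical files.
    """
    dest = Path(dest)
    dest.mkdir(parents=True, exist_ok=True)
    stops = stops.copy()
    if "participant" not in stops.columns:
        stops.insert(0, "participant", participant)
    for col in STOPS_COLUMNS:
        if col not in stops.columns:
            stops[col] = np.nan
    stops_path = dest / "stops.csv"
    daily_path = dest / "daily_features.csv"
    stops[STOPS_COLUMNS].to_csv(stops_path, index=False)
    daily.to_csv(daily_path, index=False)
    return stops_path, daily_path
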