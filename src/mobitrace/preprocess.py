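"""Preprocessing: duplicate removal and the accelerometer motion score.

The motion score summarises, per fixed-length epoch, how much physical
motion the recording device underwent: the population standard deviation
of the acceleration-vector magnitude sqrt(ax^2 + ay^2 + az^2) over the
epoch's samples.  Using the magnitude makes the score invariant under any
fixed rotation of the device (carrying orientation is arbitrary), and a
device at rest — whatever its orientation — measures constant gravity, so
its score is zero up to sensor noise.  The score is unitless-by-convention
(same units as the input axes); classifier thresholds are expressed in the
same units.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


def deduplicate(gps: pd.DataFrame) -> pd.DataFrame:
    """Collapse rows identical in (timestamp, lat, lon) to their first occurrence.

    Two samples at the same instant with different coordinates are both
    kept — they are contradictory evidence, not duplicates.  Idempotent.
    """
    return gps.drop_duplicates(subset=["timestamp", "lat", "lon"], keep="first") \
              .reset_index(drop=True)


@dataclass
class MotionSeries:
    """Per-epoch motion scores on a regular epoch grid.

    ``epoch_start`` holds the UTC start instant of each scored epoch
    (non-overlapping, ``epoch_length_s`` seconds each); ``score`` the
    non-negative motion score.  Epochs with fewer than 2 samples score 0.
    """

    epoch_start: pd.DatetimeIndex
    score: np.ndarray
    epoch_length_s: float

    def __len__(self) -> int:
        return len(self.score)

    @classmethod
    def empty(cls, epoch_length_s: float = 30.0) -> "MotionSeries":
        return cls(pd.DatetimeIndex([], tz="UTC"), np.empty(0), epoch_length_s)


def motion_score(accel: pd.DataFrame, epoch_length_s: float = 30.0) -> MotionSeries:
    """Score physical motion per epoch from raw 3-axis accelerometry.

    score(epoch) = population SD of ||a|| over the epoch's samples.
    Population (not sample) SD keeps 2-sample epochs well defined and the
    whole computation deterministic.  Epoch boundaries are aligned to
    multiples of ``epoch_length_s`` since the Unix epoch.
    """
    if epoch_length_s <= 0:
        raise ValueError(f"epoch_length_s must be positive, got {epoch_length_s}")
    if accel.empty:
        return MotionSeries.empty(epoch_length_s)
    mag = np.sqrt(accel["ax"].to_numpy() ** 2
                  + accel["ay"].to_numpy() ** 2
                  + accel["az"].to_numpy() ** 2)
    epoch_ns = int(epoch_length_s * 1e9)
    t_ns = accel["timestamp"].astype("int64").to_numpy()
    epoch_idx = t_ns // epoch_ns
    frame = pd.DataFrame({"epoch": epoch_idx, "mag": mag})
    grouped = frame.groupby("epoch")["mag"].agg(["std", "count"])
    # population SD: pandas std is ddof=1; rescale, and force <2-sample epochs to 0
    n = grouped["count"].to_numpy()
    sd = grouped["std"].to_numpy()
    score = np.where(n >= 2, np.nan_to_num(sd) * np.sqrt((n - 1) / np.maximum(n, 1)), 0.0)
    starts = pd.to_datetime(grouped.index.to_numpy() * epoch_ns, utc=True)
    return MotionSeries(pd.DatetimeIndex(starts), score, epoch_length_s)


def attach_motion(gps: pd.DataFrame, motion: MotionSeries) -> pd.DataFrame:
    """Annotate each GPS fix with the score of the epoch containing it.

    Fixes with no accelerometer coverage get NaN; the classifier treats
    NaN as "no motion evidence" and falls back to purely spatial logic, so
    an empty MotionSeries reproduces motion-free classification exactly.
    Timestamps and coordinates are never altered.
    """
    out = gps.copy()
    if len(motion) == 0:
        out["motion"] = np.nan
        return out
    epoch_ns = int(motion.epoch_length_s * 1e9)
    gps_epoch = gps["timestamp"].astype("int64").to_numpy() // epoch_ns
    score_by_epoch = pd.Series(motion.score,
                               index=motion.epoch_start.astype("int64") // epoch_ns)
    out["motion"] = score_by_epoch.reindex(gps_epoch).to_numpy()
    return out
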