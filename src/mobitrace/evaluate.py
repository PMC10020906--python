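"""Diary-ground-truth evaluation of the stop/trip classification.

A participant-kept stop diary (begin/end instants plus coordinates of each
stay) serves as ground truth.  Evaluation happens on two levels:

* **per sample** — every GPS fix gets a truth label (stop iff it falls
  inside a diary stop, closed interval) and a predicted label; confusion
  counts give percent correct, balanced accuracy and F1 (positive class
  = stop).
* **per interval** — detected stops are matched against diary stops:
  a detected stop is *correct* when its temporal overlap with some diary
  stop reaches half of the shorter of the two durations; a diary stop is
  *missed* when no detected stop touches it at all and *fragmented* when
  two or more detected stops touch it.  Diary trips are the gaps between
  consecutive diary stops; a diary trip is *missed* when no detected trip
  overlaps it.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .stopgo import STOP, TRIP, StopInterval, TripInterval


@dataclass
class ConfusionCounts:
    """Binary confusion counts; positive class = stop."""

    tp: int = 0
    tn: int = 0
    fp: int = 0
    fn: int = 0

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass
class SampleMetrics:
    counts: ConfusionCounts
    percent_correct: float
    balanced_accuracy: float
    f1: float


@dataclass
class IntervalMatchReport:
    """Interval-level accounting of detected vs diary stops and trips."""

    diary_stops: int
    detected_stops: int
    correct_stops: int
    missed_stops: int
    fragmented_stops: int
    diary_trips: int
    detected_trips: int
    missed_trips: int


def ground_truth_labels(gps: pd.DataFrame, diary: pd.DataFrame) -> np.ndarray:
    """Label every GPS sample from the diary: stop iff inside a logged stay.

    Diary intervals are closed on both ends — a fix exactly at a begin or
    end instant is a stop.
    """
    t = gps["timestamp"].to_numpy()
    labels = np.full(len(gps), TRIP, dtype="<U4")
    for begin, end in zip(diary["begin"].to_numpy(), diary["end"].to_numpy()):
        labels[(t >= begin) & (t <= end)] = STOP
    return labels


def sample_metrics(predicted: np.ndarray, truth: np.ndarray) -> SampleMetrics:
    """Per-sample classification metrics against ground-truth labels.

    Metrics whose denominator is zero (e.g. no true stops at all) are
    reported as NaN rather than 0.
    """
    predicted = np.asarray(predicted)
    truth = np.asarray(truth)
    if len(predicted) != len(truth):
        raise ValueError(f"predicted ({len(predicted)}) and truth ({len(truth)}) "
                         "length mismatch")
    p_stop = predicted == STOP
    t_stop = truth == STOP
    c = ConfusionCounts(
        tp=int(np.sum(p_stop & t_stop)),
        tn=int(np.sum(~p_stop & ~t_stop)),
        fp=int(np.sum(p_stop & ~t_stop)),
        fn=int(np.sum(~p_stop & t_stop)),
    )
    total = c.total
    percent = 100.0 * (c.tp + c.tn) / total if total else np.nan
    sens = c.tp / (c.tp + c.fn) if (c.tp + c.fn) else np.nan
    spec = c.tn / (c.tn + c.fp) if (c.tn + c.fp) else np.nan
    balanced = (sens + spec) / 2.0
    f1_den = 2 * c.tp + c.fp + c.fn
    f1 = 2.0 * c.tp / f1_den if f1_den else np.nan
    return SampleMetrics(c, percent, balanced, f1)


def _overlap_s(a_start, a_end, b_start, b_end) -> float:
    return max(0.0, (min(a_end, b_end) - max(a_start, b_start)).total_seconds())


def match_intervals(detected_stops: Sequence[StopInterval],
                    detected_trips: Sequence[TripInterval],
                    diary: pd.DataFrame,
                    overlap_frac: float = 0.5) -> IntervalMatchReport:
    """Match detected intervals against the diary and count outcomes.

    ``overlap_frac`` is the correctness criterion: a detected stop is
    correct when its overlap with some diary stop is at least this fraction
    of the shorter of the two durations.
    """
    diary_iv = list(zip(diary["begin"], diary["end"])) if len(diary) else []

    correct = 0
    touches = np.zeros(len(diary_iv), dtype=int)
    for s in detected_stops:
        s_dur = (s.end - s.start).total_seconds()
        is_correct = False
        for j, (b, e) in enumerate(diary_iv):
            ov = _overlap_s(s.start, s.end, b, e)
            if ov > 0:
                touches[j] += 1
                shorter = min(s_dur, (e - b).total_seconds())
                if shorter > 0 and ov >= overlap_frac * shorter:
                    is_correct = True
        correct += int(is_correct)

    missed = int(np.sum(touches == 0))
    fragmented = int(np.sum(touches >= 2))

    # diary trips = gaps between consecutive diary stops
    diary_trips = [(diary_iv[j][1], diary_iv[j + 1][0]) for j in range(len(diary_iv) - 1)
                   if diary_iv[j + 1][0] > diary_iv[j][1]]
    missed_trips = 0
    for b, e in diary_trips:
        if not any(_overlap_s(t.start, t.end, b, e) > 0 for t in detected_trips):
            missed_trips += 1

    return IntervalMatchReport(
        diary_stops=len(diary_iv), detected_stops=len(detected_stops),
        correct_stops=correct, missed_stops=missed, fragmented_stops=fragmented,
        diary_trips=len(diary_trips), detected_trips=len(detected_trips),
        missed_trips=missed_trips)


def benchmark_report(run_with_motion, run_without_motion, diary: pd.DataFrame,
                     overlap_frac: float = 0.5) -> pd.DataFrame:
    """Side-by-side accuracy table for the two classifier configurations.

    Each run is a (stops, trips, labeled_gps) triple from
    :func:`mobitrace.stopgo.run_stop_go` on identical GPS input; rows cover
    per-sample metrics and the interval accounting for both configurations.
    """
    rows = {}
    for name, (stops, trips, labeled) in (("with_motion", run_with_motion),
                                          ("without_motion", run_without_motion)):
        truth = ground_truth_labels(labeled, diary)
        m = sample_metrics(labeled["label"].to_numpy(), truth)
        r = match_intervals(stops, trips, diary, overlap_frac)
        rows[name] = {
            "correct_n": m.counts.tp + m.counts.tn,
            "total_n": m.counts.total,
            "percent_correct": m.percent_correct,
            "balanced_accuracy": m.balanced_accuracy,
            "f1": m.f1,
            "detected_stops": r.detected_stops,
            "diary_stops": r.diary_stops,
            "correct_stops": r.correct_stops,
            "missed_stops": r.missed_stops,
            "fragmented_stops": r.fragmented_stops,
            "detected_trips": r.detected_trips,
            "diary_trips": r.diary_trips,
            "missed_trips": r.missed_trips,
        }
    return pd.DataFrame(rows)
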