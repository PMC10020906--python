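# mobitrace

Smartphone GPS + accelerometer mobility analytics for health research:
from raw timestamped sensor records to stop/trip segmentation, a daily
life-space variable table, and a diary-ground-truth evaluation harness —
plus a seeded synthetic study simulator so the entire pipeline can be
developed and tested without field data.

## Who this is for

Mobility is an increasingly common outcome in ageing, rehabilitation and
mental-health studies: participants carry an inexpensive smartphone that
logs a GPS fix every 10 s and 1 Hz 3-axis accelerometry for days to weeks,
and the analysis has to turn those records into interpretable per-day
variables (time out of home, number of distinct places visited, life-space
area, ...). `mobitrace` implements that analysis end to end as a tested
Python library and CLI.

## The core method

**Stop & Go classification.** A *stop* is a period of more than 5 minutes
spent within a 100 m-radius area; a *trip* is any period of movement
between stops. Every GPS sample is labelled by a greedy running-centroid
run detector (a fix joins the current run while it is within 100 m of the
run's centroid), candidate runs are duration-filtered (> 300 s, strict) and
their boundaries refined against the run's robust radial scatter. The
accelerometer is reduced to a per-epoch **motion score** — the population
standard deviation of the acceleration magnitude ‖a‖ = √(ax²+ay²+az²) over
30 s epochs, zero at rest and orientation-invariant — and fused into the
spatial classification: stops with sustained high motion are demoted to
trips, and trip gaps between co-located stops with at-rest motion are
bridged. The fusion suppresses *fragmented stops*, single true dwells that
GPS noise splits into several detected stops.

**Daily variables.** From the labelled samples and intervals the package
computes, per participant-day: max/avg distance from home, convex-hull
life space (perimeter P, area A, Polsby–Popper compactness 4πA/P²), a
robust standard deviational ellipse area (minimum covariance determinant
scatter Σ scaled to its support, area = π·s²·√det Σ), 200 m-buffered daily
path area, revisited life-space %, location counts from greedy 100 m
clustering, dwell-time location entropy H = −Σ pᵢ ln pᵢ, time at/out of
home, foot-bike vs vehicle trip time (median-speed split at 20 km/h),
first-move time, most-active time of day, and revisited-path %.

**Evaluation.** Given a stop diary (begin/end + coordinates per stay), the
package labels every sample from the diary, reports percent correct,
balanced accuracy and F1 (positive class = stop), and matches detected
against diary stops (correct / missed / fragmented, missed trips) — with
and without the motion score.

## Worked example

```python
from mobitrace import (SimConfig, simulate_study, run_stop_go,
                       ground_truth_labels, sample_metrics, match_intervals,
                       compute_daily_features)

study = simulate_study(SimConfig(seed=42, n_days=3))
print(f"{len(study.gps)} GPS fixes, {len(study.accel)} accel samples, "
      f"{len(study.diary)} diary stops")

stops, trips, labeled = run_stop_go(study.gps, study.accel)
print(f"detected {len(stops)} stops and {len(trips)} trips")

m = sample_metrics(labeled["label"].to_numpy(),
                   ground_truth_labels(labeled, study.diary))
print(f"percent correct {m.percent_correct:.2f}, "
      f"balanced accuracy {m.balanced_accuracy:.3f}, F1 {m.f1:.3f}")

r = match_intervals(stops, trips, study.diary)
print(f"correct stops {r.correct_stops}/{r.detected_stops}, "
      f"missed {r.missed_stops}, fragmented {r.fragmented_stops}")

daily = compute_daily_features(labeled, stops, trips)
print(daily[["date", "n_locations", "time_out_of_home_s",
             "hull_area_m2", "location_entropy"]].round(3).to_string(index=False))
```

prints

```
25419 GPS fixes, 259200 accel samples, 11 diary stops
detected 11 stops and 10 trips
percent correct 99.94, balanced accuracy 0.994, F1 1.000
correct stops 11/11, missed 0, fragmented 0
      date  n_locations  time_out_of_home_s  hull_area_m2  location_entropy
2022-03-01            7             35650.0   5235961.854             0.818
2022-03-02            3             15150.0    339049.050             0.405
2022-03-03            3              4500.0    220666.247             0.145
```

The simulated participant made 11 diary-logged stays over three days; the
classifier recovered all 11 (none missed, none fragmented) and labelled
99.94% of the 25,419 GPS samples correctly. The daily rows show the stop
count, seconds away from home, convex-hull life-space area in m² and the
entropy of dwell time over distinct locations.

The same pipeline runs from the shell:

```sh
mobitrace simulate --seed 42 --n-days 3 --out data/
mobitrace evaluate --gps data/gps.csv --accel data/accel.csv \
                   --diary data/diary.csv --out results/
mobitrace run --config pipeline.toml          # full pipeline from one config
```

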