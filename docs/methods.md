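# Methods

## Problem setting and assumptions

The package processes recordings from a phone carried by one participant:
GPS fixes at a nominal 10-second interval (WGS84, position noise on the
order of 10 m under open sky, worse in narrow streets and rural terrain)
and 1 Hz 3-axis accelerometry in arbitrary carrying orientation. Analysis
is per participant; all timestamps are held in UTC internally and converted
to a configured study time zone only for day boundaries and time-of-day
variables. Recording is assumed continuous apart from dropout and charging
gaps; gaps longer than 30 minutes split the data into sessions that are
analysed independently.

## Stop & Go classification

A stop is defined as strictly more than 5 minutes spent within a
100 m-radius area; every other covered period is a trip. The classifier:

1. **Run detection.** Scanning fixes in time order, a fix joins the current
   run while its haversine distance to the run's running centroid is at
   most `stop_radius_m`; otherwise it founds a new run. Runs spanning more
   than `min_stop_duration_s` are stop candidates. The centroid is the
   arithmetic mean of latitude/longitude, which at a 100 m scale differs
   from the true spherical mean by far less than GPS noise.
2. **Boundary refinement.** At walking speed the approach to and departure
   from a dwell keeps fixes inside the radius for up to ~2 minutes, so raw
   run boundaries overhang the true dwell. Edge fixes whose distance to the
   centroid strictly exceeds `trim_k` (default 3) times the run's robust
   radial scatter — median member distance divided by 1.177, the median
   radius of a 2-D Gaussian — are returned to the trip class. Trimming
   iterates to a fixpoint because the un-trimmed edges bias both the
   centroid and the scatter; on noise-free data the scatter converges to 0
   and recovery is exact to one sampling period (a property the test suite
   asserts). The strict `>` comparison keeps zero-scatter dwells intact.
3. **Motion fusion** (optional). The accelerometer is summarised per 30 s
   epoch as the population standard deviation of the acceleration-vector
   magnitude: orientation-invariant, zero at rest regardless of gravity
   direction, and requiring no calibration of axis units. Two rules use it:
   a candidate stop whose median epoch score exceeds the motion threshold
   is demoted to trip (movement confined to a small area, e.g. slow
   traffic), and a trip gap between two stops whose centroids lie within
   `stop_radius_m` is relabelled stop when its median score is at or below
   the threshold — this bridges GPS noise excursions and is the mechanism
   that suppresses fragmented stops. Samples without accelerometer coverage
   never flip a label, so motion-free input degenerates exactly to the
   purely spatial classifier.

**Motion threshold.** The score's units depend on the device, so the
default threshold is data-adaptive: Otsu's method applied to the epoch-score
distribution, which places the split between the at-rest and in-motion
modes wherever they sit on the device's scale. A fixed percentile was
considered and rejected: when at-rest epochs dominate the recording (a
device at home most of the day), any low percentile falls inside the rest
mode, so roughly half of genuine rest epochs exceed it and both fusion
rules misfire. Otsu needs two separable modes to be meaningful, so a guard
skips motion fusion entirely when the mean score above the split is less
than twice the mean below it (e.g. a recording with no trips at all). An
explicitly configured `motion_threshold` bypasses both the derivation and
the guard.

**Aggregation.** Maximal constant-label runs become intervals. Stop runs
spanning ≤ `min_stop_duration_s` are relabelled trip; consecutive stops
separated by less than `merge_gap_s` whose centroids are within
`stop_radius_m` are merged, absorbing the samples between them. Within a
session, interval k ends exactly where interval k+1 starts (the first
sample of the next run), so stops and trips tile the covered time with no
gap or overlap; the last interval ends at its final sample. No interval
spans a session boundary and gap time belongs to no interval. One
consequence of the bridging rules is accepted deliberately: a stop that
absorbed a noise excursion can contain member fixes farther than
`stop_radius_m` from its centroid; the radius-containment property is
therefore asserted only for motion-free runs.

### Classifier parameters

| parameter | default | units | rationale |
|---|---|---|---|
| `min_stop_duration_s` | 300 (strict >) | s | the stop definition; 300 s exactly is a trip |
| `stop_radius_m` | 100 | m | the stop definition's spatial scale |
| `merge_gap_s` | 120 | s | bridges one-to-two missed sampling windows between co-located stops |
| `motion_threshold` | data-adaptive (Otsu) | score units | device-dependent scale, see above |
| `motion_epoch_s` | 30 | s | long enough for a stable SD at 1 Hz, short against the 300 s stop scale |
| `session_gap_s` | 1800 | s | phones off or charging; no interval should span such a gap |
| `trim_k` | 3 | — | 3σ of the radial scatter; < 1% false trims under Gaussian noise |

## Daily variables

All planar geometry is computed in one study-wide azimuthal equidistant
projection centred on the point cloud (implemented in `mobitrace.geo`;
exact in distance from the centre, error well below GPS noise within
50 km) and delegated to shapely. Day boundaries fall at local midnight of
the configured time zone; intervals crossing midnight contribute their
clipped part to each day.

- **Home** is the location cluster with the greatest dwell between 00:00
  and 06:00 local (ties: greater total dwell; no night dwell anywhere:
  greatest total dwell, logged). Configured coordinates override detection.
- **Location clusters** come from greedy sequential clustering of stop
  centroids (first cluster within 100 m wins, dwell-weighted centroid
  update). A location is *revisited* when its cluster is visited at least
  twice across the study — the per-day count follows the variable's name
  rather than a per-day re-count.
- **Convex hull**: perimeter, area, and Polsby–Popper compactness
  4πA/P² ∈ (0,1]; the hull degenerates (area 0, compactness missing) below
  three non-collinear points.
- **Standard deviational ellipse**: minimum covariance determinant location
  and scatter (scikit-learn `MinCovDet`, fixed random state; empirical
  moments below 10 points or on degenerate scatter), scaled to the largest
  Mahalanobis distance among support points: area = π·s²·√det Σ. The area
  is invariant to uniform rescaling of Σ, so only the scatter's shape and
  the support enter. Scatter thinner than 1 mm in any direction yields 0.
- **Daily path area**: each trip's fixes (clipped to the day) buffered by
  200 m with round caps, all buffers dissolved by union. Water-body
  removal is not performed (no hydrology layer is bundled).
- **Revisited life space**: per day, 100 · area(hull_d ∩ ⋃ other hulls) /
  area(hull_d), plus the average over days with valid hulls.
- **Mode split**: a trip is vehicle when the median of its consecutive-leg
  speeds strictly exceeds 20 km/h, else foot/bike (ties to foot/bike); the
  threshold is configurable since the boundary between fast cycling and
  slow urban driving is fuzzy.
- **Location entropy**: H = −Σ pᵢ ln pᵢ over the day's dwell distribution
  across clusters, in nats (base e chosen; any base is defensible).
- **Revisited paths**: trips keyed by their unordered (origin, destination)
  cluster pair — the cheapest reading of "identical trips"; geometric path
  overlap is out of scope. Trips missing an adjacent stop (study edges)
  are excluded from numerator and denominator.
- **Time bins**: first-move time is the local start of the day's first
  trip; the most-active period is the arg-max of trip starts over morning
  [05–11), noon [11–17), evening [17–23), ties to the earlier bin.

## Evaluation against a diary

Ground truth labels every sample stop iff it lies inside a diary stay
(closed intervals on both ends). Per-sample metrics are percent correct,
balanced accuracy (mean of sensitivity and specificity) and F1 with stop as
the positive class; zero-denominator metrics are reported missing, never 0.
At interval level, a detected stop is *correct* when its temporal overlap
with some diary stop reaches at least 50% of the shorter of the two
durations (the criterion is configurable — "similar time interval" admits
several operationalisations); a diary stop is *missed* when nothing touches
it and *fragmented* when two or more detected stops touch it, so each diary
stop falls in exactly one category (fragmented takes precedence over singly
matched). Diary trips are the gaps between consecutive diary stops. Samples
outside every diary day carry no ground truth and are excluded.

## The synthetic study simulator

The generator emulates the recording conditions the pipeline is built for:
a participant who alternates dwells at a handful of fixed places (one home,
places 0.4–5 km away) with straight-line trips; roughly 2.3 excursions per
day (≈5–6 diary stops/day), dwell means 25 min–4 h per place, 15% of visits
shorter than 5 minutes (which by definition belong to trips and exercise
the duration filter); foot/bike speeds 3–16 km/h and vehicle speeds
25–60 km/h with vehicle probability 0.35; GPS fixes every 10 s with
isotropic 10 m Gaussian noise and 2% dropout; 1 Hz accelerometry as gravity
plus per-axis Gaussian noise with σ = 0.05 m/s² at rest and 0.8 m/s² in
motion. Every dwell longer than 5 minutes is written to the ground-truth
diary. A `degrade` step overlays extra Gaussian noise and heavy-tailed
position bursts (uniform magnitude up to 300 m) without touching ground
truth, emulating poor reception. One `numpy` Generator seeded from
`SimConfig.seed` drives everything, so identical configs are bit-identical.

What the simulator does **not** model — and what passing tests therefore do
not establish about field data: road-network geometry and map-matched
paths, autocorrelated (multipath/urban-canyon) GPS error, gradual
walking-speed variation, device-specific accelerometer artefacts, missed
diary entries or diary timing error, and multi-participant heterogeneity.
Accuracy numbers on synthetic studies characterise the implementation
under its stated noise model, not expected field performance.

The per-day `truth_features` bookkeeping covers the schedule-derivable
variables (counts, durations, entropy, distances, first-move time, mode
times, most-active bin). The scatter-dependent geometry variables (hull,
ellipse, daily path area, revisited life space) have no schedule-level
ground truth — they depend on realised noise — and are instead validated
against closed forms and independent oracles (Khachiyan minimum-ellipse,
capsule area, direct entropy summation) in the test suite.

## Numerical choices and degenerate inputs

- Haversine distances on the WGS84 mean radius 6,371,008.8 m.
- Population (not sample) SD in the motion score keeps 2-sample epochs
  defined; epochs with fewer than 2 samples score 0.
- A single GPS sample is labelled stop (zero span) but aggregates to a
  zero-duration interval that fails the stop duration filter.
- Hull areas below 10⁻⁶ m² (projection round-off on collinear input) are
  treated as degenerate.
- Timestamps parse as ISO-8601 or epoch seconds/milliseconds, auto-detected
  per file; study windows given as dates are closed on both whole days.
- Interval tables are written with fixed column order and formatting, so
  identical inputs give byte-identical outputs.

## Problem sizes in the shipped checks

The test suite and the acceptance script run on simulated studies of 2–7
days (≈8,600 fixes and 86,400 accelerometer samples per day): 100 days for
the partition/conservation sweep, ten 7-day studies for the per-sample F1
bar, twenty 2-day degraded replicates for the fragmentation-ordering check,
and a one-week study for the headline evaluation. These sizes give stable
counts while keeping a full run in the low minutes on one core.

## Known limitations

- The classifier is single-pass and greedy; a dwell straddling a session
  boundary is reported as two stops.
- Centroid averaging of raw latitude/longitude is inappropriate near the
  180° meridian and the poles; studies there should re-map longitudes
  first.
- Mode split by median speed cannot separate fast cycling from slow
  driving, and stop-and-go traffic can fall below the vehicle threshold.
- The revisited-path definition ignores the route actually taken.
- Daily path area includes water bodies and other non-traversable surface.
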