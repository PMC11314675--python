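# Methods

This note documents the models and procedures implemented in `stridemap`,
the parameters that matter, what the synthetic data does and does not
emulate, and the design decisions taken where the problem left room.

## 1. Stride segmentation

The detector observes a single signal: the sagittal-plane inclination
(pitch) of the thigh of one instrumented leg.  At maximum thigh pitch the
heel is close to striking the ground, so pitch maxima mark stride starts;
"one step" throughout the package means a full stride of that leg.
Detection is peak picking (`scipy.signal.find_peaks`) with three
thresholds:

| parameter | default | unit | role |
|---|---|---|---|
| `min_height` | 1.6 | rad | reject sub-maximal swings |
| `prominence` | 0.2 | rad | reject noise ripples on the flank |
| `min_separation` | 16 | samples | one event per stride (~0.53 s at 30 Hz) |
| `max_cycle_duration` | 2.0 | s | longer gaps are standing, not a stride |

`min_separation` is expressed in samples, not seconds, matching the
deployed configuration at the nominal ~30 Hz rate; at other rates it should
be overridden.  Plateaus of equal consecutive maxima yield their first
sample (a deterministic tie-break).  Windows span peak to peak, half-open
`[start, end)`; a gap of ≥ 2 s produces no window.  The 1.6 rad threshold
exceeds 90°, which implies a mounting/offset convention in the sensor
frame; the synthetic generator simply honours the threshold rather than
modelling the convention.

## 2. Features, scaler, classifiers

Each window is reduced to minimum, maximum, mean, standard deviation and
range of the shank and thigh inclination — 10 features in a fixed order
(shank block first).  Gyroscope and acceleration channels are ingested and
stored but excluded from the vector; they did not survive correlation
screening against the targets.  Standard deviation uses the population
convention (divide by n).

The scaler is min–max to [0, 1], fitted on the **training fold only** of
every cross-validation run and applied unchanged to the test fold, so no
information leaks across the subject split.  Test values outside the
training range are not clipped (ordering information is preserved);
zero-range training columns map every input to 0 (a deterministic guard
against division by zero).

Two model families are provided: an RBF-kernel SVM (C = 1) in one-vs-rest
configuration — ties resolved by the highest decision score, then by the
fixed class order walk < stairs_up < stairs_down — and a decision tree with
maximum depth 3.  The kernel and regularisation are exposed defaults, not
tuned values; results of interest here are protocol-level.  No class
re-weighting is applied even though level walking contributes roughly twice
as many strides as either stairs class.  Training sorts samples into a
canonical order first, so shuffled inputs produce bit-identical models.

**Protocols.**  LOSO: one run per subject, training on all other subjects.
LOTO: one run per trial, training on all trials of all *other* subjects —
the tested subject's remaining trials are excluded too, keeping the split
subject-disjoint.  Reports carry per-run accuracy and macro precision/
recall/F1 over the three targets (zero-denominator classes contribute 0),
mean/std/min/max across runs, and the element-wise sum of the per-run 3×3
confusion matrices (rows true, columns predicted).

## 3. Georeferencing

GPS fixes arrive more slowly than strides, so fix coordinates are linearly
interpolated in time to each step's timepoint, per coordinate in degrees;
at step scale the curvature error is far below GPS noise.  The step is
anchored at the window's **start** time (the heel strike that opens the
stride).  Step times outside the fix span are dropped by the pipeline (and
rejected with an explicit error by the low-level interpolation).  IMU and
GPS are assumed to share a clock; a constant offset parameter absorbs a
known shift.  GPX 1.1 is read and written with the standard library XML
tools; classified steps export as GeoJSON points (walking red, stairs
green).

## 4. The map layer

Paths are polylines of ≥ 2 WGS84 points with a type (`trail`, `walk`,
`stairs_up`, `stairs_down`), a property map (stairs carry an integer
`stair_count`), a merge count ≥ 1, and optional crossing links at both
ends.  Crossings store their location explicitly — the stored location is
authoritative over implied path endpoints — and the set of (path, end)
connections.  Referential symmetry (crossing ↔ path back-references) is
maintained by construction and verified by a global audit that also checks
for orphan crossings and zero-length paths.

Persistence is a GeoJSON FeatureCollection (RFC 7946, longitude-latitude
order): LineString features for paths, Point features for crossings.  The
in-memory `MapStore` implements the storage contract (insert, delete,
update, get-by-id, bounding-box query); a database backend could replace it
behind the same surface.  Metric computations use an equirectangular local
tangent frame centred on the data; at sub-kilometre extents its deviation
from a true azimuthal projection is negligible, while stored coordinates
remain WGS84 degrees.

## 5. Insertion algorithm

Inserting one path runs, atomically (all-or-nothing on a store snapshot):

1. **Simplify** — cut the polyline at self-intersections into simple
   pieces (earliest-crossing walk over the segments), then Douglas–Peucker
   each piece with `simplify_tolerance` (0.5 m); endpoints are preserved
   and concatenated pieces cover the input.
2. **Candidates** — bounding-box query, padded by `match_distance` so that
   thin boxes of straight paths running parallel to the new one are not
   missed.
3. **Match** — sample the segment every `resample_spacing` (1 m).  A
   sample matches a candidate through a specific candidate segment: its
   perpendicular projection must fall within that segment (±½ spacing),
   the offset must be ≤ `match_distance` (5 m) and the headings must agree
   within `match_angle` (45°, modulo 180° — paths are bidirectional).
   Requiring an in-segment projection stops a stretch that merely passes a
   path's endpoint from "matching around the corner", which keeps matched
   interval boundaries accurate to about the sampling step.  Matching runs
   shorter than `min_match_length` (3 m) are demoted to unmatched.  The
   sample headings of the new path use a short chord (`heading_window`,
   2 m) so GPS jitter does not dominate the direction estimate.
4. **Execute** — unmatched stretches are inserted as new paths with merge
   count 1.  For a matched stretch the candidate is split at the match
   boundaries, the coinciding parts are merged (vertices resampled at
   `resample_spacing`, paired by arc-length fraction, re-oriented if
   anti-parallel, averaged with merge-count weights; numeric properties
   averaged with the same weights, `stair_count` rounded; merge counts
   add), and the consumed inputs are deleted.  Connectors are inserted at
   every boundary between matched and unmatched parts and at candidate
   split points; a connector within `crossing_snap` (2 m) of an existing
   crossing reuses it, which curbs connector proliferation at noisy
   junctions.  A path end that already holds a link keeps it.
5. **Audit** — the consistency audit must pass or the insertion rolls
   back.

Paths of different types never merge by default (`respect_path_types`);
a stairs path is a different facility from the walkway beside it.  The
untyped mode (`respect_path_types=False`) treats everything as a simple
trail, the configuration used for trace-only map building.  On merges in
untyped mode the heavier path donates its type and non-numeric properties.

Pairwise merges inside a merge group run in a fixed order (the weighted
average makes the order nearly neutral; fixing it gives determinism).
`prune_unmerged(store, k)` removes paths with merge count < k — the
mechanism for discarding reflection artefacts, which typically match
nothing and stay at merge count 1 — and drops crossings that lose their
last connection.

**Raw traces** are converted to paths with a centred moving average over
`trace_smooth_window` (5) fixes, shrinking near the ends so the endpoints
stay anchored.  With σ = 2 m fix noise this roughly halves the residual
error and, more importantly, makes local headings meaningful for the
matching criterion.

## 6. Evaluation metric

`evaluate_map(constructed, truth, buffer)` returns geometric correctness —
the fraction of constructed path length inside the union buffer (default
5 m) around the reference paths — and topological correctness — the
fraction of reference crossings with a constructed crossing within the
buffer.  A reference without crossings scores topological correctness 1
vacuously.

## 7. Synthetic data

The gait generator produces rectified-sinusoid inclination signals: one
stride of period T contributes A·|sin(πt/T)| on the thigh, with
class-conditional parameters

| class | period (s) | thigh peak (rad) | shank amp (rad) | shank offset (rad) | shank phase (rad) |
|---|---|---|---|---|---|
| walk | 1.1 | 1.8 | 1.00 | 0.00 | 0.0 |
| stairs_up | 1.4 | 2.1 | 1.20 | +0.45 | +0.5 |
| stairs_down | 1.2 | 1.9 | 0.85 | −0.45 | −0.5 |

plus additive Gaussian sensor noise (σ = 0.05 rad) and a per-subject
multiplicative amplitude factor (σ = 0.08).  The effective thigh peak is
floored at 1.6 + 3σ_noise + 0.02 rad so detection stays well-posed for
every simulated subject; the floor slightly compresses inter-subject walk
variability at the low end, which the shank offsets compensate for in
class separability.  Gyroscope channels carry the waveform derivative and
acceleration channels a scaled second derivative plus gravity, so the full
trial CSV schema is exercised even though those channels are unused
downstream.  Bouts of different activities are separated by a 3 s standing
gap (longer than the maximum cycle duration) so stride windows never
straddle two activities; the gap can be set to 0 for continuous routes.
The default per-trial schedule (24 walk / 12 up / 12 down strides)
reproduces the roughly 2:1:1 class imbalance of corridor-and-staircase
protocols.

Ground-truth networks come as three templates: `corridor_with_stairs`
(a 46 m hallway flanked by two 8 m staircases of 21 steps each; 3 paths,
2 crossings), `plus_junction` (four 60 m walkways meeting at one crossing —
the fixture for junction-recovery experiments), and `campus_grid` (a 2×2
block grid: 12 edges, 9 crossings).  GPS traces are sampled along a route
at walking speed (1.3 m/s) and fix interval (1 s) with isotropic Gaussian
noise (σ = 2 m) and, with a per-trace probability, a contiguous run of
fixes displaced 25 m perpendicular to the local route direction — the
signature of a multipath reflection off a facade.  All generators are pure
functions of their parameters and seed.

**What the synthetic data does not emulate:** biomechanically realistic
joint kinematics, soft-tissue and mounting artefacts, inter-stride
correlation structure, heteroscedastic or urban-canyon-correlated GPS
error, fix dropouts, and sitting/standing activities.  Perfect LOSO scores
on the generator therefore demonstrate that the pipeline's plumbing,
protocols and bookkeeping are sound — not that real three-class accuracy
is 100%.  The stochastic thresholds used in the tests (LOSO accuracy
≥ 0.90; geometric correctness ≥ 0.9 at a 5 m buffer) are implementation
choices for these study conditions, standing in for field results that
require a recorded dataset.

## 8. Problem sizes and numerical choices

The test suite and the acceptance script run at desk scale: 100 seeded
trials for stride recovery, 20 subjects × 2 trials (≈ 1800 strides) for
the classifier protocols, 10 noisy traces over the 4-path junction for
map recovery, and 20 random 50-operation sequences for the consistency
audit.  Matching and merging sample at 1 m; split positions interpolate
linearly between vertices (length conservation holds to well under 1 cm at
these scales); integer apportionment of `stair_count` uses largest
remainders so parts always sum exactly to the original.  Degenerate
inputs — windows shorter than 2 samples, empty training sets, split
positions at or beyond an endpoint, routes that do not connect — raise
typed errors rather than propagating NaNs.

## 9. Known limitations

* Connector placement inherits the noise of the match boundary; nearby
  connectors are coalesced within 2 m, but a very noisy junction can still
  produce more than one crossing (topological evaluation tolerates this by
  asking only for *a* crossing within the buffer).
* Fragment cleanup beyond `prune_unmerged` (short sliver paths left at
  partial-match boundaries) is out of scope, as is open-area/plaza
  handling, where trace bundles do not form a line at all.
* The navigation layer (global/per-user route graphs on top of the map) is
  a concept the data model anticipates (bidirectional path/crossing graph)
  but is not implemented here.
* Property updating on merge uses the same weighted average as the
  geometry; alternatives (e.g. max-count for stairs) may be preferable
  once real stair-count observations exist.
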