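# stridemap

Tools for context-aware pedestrian movement analysis: per-stride **human
activity recognition** (HAR) from two leg-mounted IMUs, and **iterative
construction of a geographic path network** from GPS traces of walked
routes.  The intended consumers are wearable-robotics and gait-analysis
groups that want a map of *where* people walk, climb and descend — so a
lower-limb exoskeleton or active orthosis can anticipate an activity switch
from location history instead of reacting to it.

## What it computes

**Stage 1 — activity recognition per stride.**  Two IMUs on the thigh and
shank record sagittal-plane inclination, angular velocity and acceleration
at ~30 Hz.  Step events are local maxima of the thigh pitch angle θ_thigh
(heel strike is imminent at maximum thigh pitch), detected with height
≥ 1.6 rad, prominence ≥ 0.2 rad and a minimum separation of 16 samples.
Each pair of events closer than 2 s bounds one stride window; over each
window the feature vector

x = (min, max, mean, σ, range) of θ_shank and θ_thigh  ∈ ℝ¹⁰

is extracted, min–max scaled to [0, 1] on the training fold, and classified
into {level walking, stairs ascending, stairs descending} by an RBF SVM in
one-vs-rest configuration (or a depth-3 decision tree).  Evaluation uses
leave-one-subject-out (LOSO) and leave-one-trial-out (LOTO) protocols with
macro-averaged precision/recall/F1 and summed confusion matrices.

**Stage 2 — map construction.**  Classified steps are georeferenced by
linear interpolation of GPS fixes to the step timepoints, grouped into
activity-typed polylines, and inserted into a path network (paths = edges,
crossings = nodes of a bidirectional graph).  A new trace is simplified
into loop-free segments; each segment is partitioned into stretches that
*match* an existing path (lateral offset ≤ 5 m and heading difference
≤ 45° mod 180°) and stretches that match nothing.  Matching stretches are
merged by a merge-count-weighted vertex average,

v = (m_a·v_a + m_b·v_b) / (m_a + m_b),   m = m_a + m_b,

non-matching stretches become new paths, and connectors (crossings) are
inserted wherever matching and non-matching parts meet.  Paths that never
merge can be pruned as suspected GPS artefacts (multipath reflections).
Maps are scored by *geometric correctness* (fraction of constructed length
within a buffer of the reference network) and *topological correctness*
(fraction of reference crossings recovered within the buffer).

A synthetic-data module generates labelled gait signals, ground-truth
networks and noisy GPS traces, so the whole pipeline is testable without a
recorded study dataset.

## Worked example

```python
import stridemap as sm

# --- stage 1: LOSO evaluation on 10 synthetic subjects -------------------
samples = sm.generate_labeled_dataset(n_subjects=10,
                                      params=sm.GaitGeneratorParams(seed=1))
report = sm.evaluate_loso(samples, model_kind="svm_ovr", seed=1)
s = report.summary()
print(len(samples), report.n_runs)            # 450 strides, 10 runs
print(round(s["accuracy"]["mean"], 3))        # 1.0
print(report.confusion.tolist())              # [[230,0,0],[0,110,0],[0,0,110]]

# --- stage 2: rebuild a plus-junction network from noisy traces ----------
net = sm.generate_truth_network("plus_junction")
cfg = sm.BuilderConfig(respect_path_types=False)   # untyped "trail" mode
store = sm.MapStore()
pids = sorted(net.paths)
for i, (a, b) in enumerate([(0,1),(1,2),(2,3),(3,0),(0,2),(1,3)]):
    fixes = sm.generate_gps_trace(net, [pids[a], pids[b]],
                                  sm.TraceGeneratorParams(seed=10 + i,
                                                          reflection_probability=0.0))
    sm.insert_path(store, sm.trace_to_path(fixes, "trail",
                                           cfg.trace_smooth_window), cfg)
geo, topo = sm.evaluate_map(store, net, buffer=5.0)
print(round(geo, 3), round(topo, 3))          # 1.0 1.0
```

The LOSO report says every held-out subject's strides were classified
correctly (the three diagonal confusion blocks are the 230 walking and
2 × 110 stairs strides).  The map run folds six traces with σ = 2 m GPS
noise into a network whose entire length lies within 5 m of the true
plus-junction and whose central crossing is recovered (`topo = 1.0`).

The same pipeline is scriptable from the shell (`stridemap --help`):
`simulate-gait`, `extract-features`, `train`, `evaluate`, `classify-georef`,
`simulate-traces`, `build-map`, `prune-map`, `eval-map`, `export`.

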