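# kennelmot

Identity-consistent multi-animal, multi-camera tracking and behavioral
analytics for kennel video monitoring.

Continuous video monitoring of group-housed dogs in preclinical safety
studies needs one thing above all: every downstream readout — activity,
posture, behavior, clinical signs — must be attributed to the *right
animal on every frame*, even when animals cross, cluster, or move
between adjacent camera views. `kennelmot` implements that layer. It
consumes confidence-bearing detection streams (from any object detector
plus appearance classifier — e.g. colour/reflective-pattern harness
recognition — or from its built-in simulator) and provides:

* **Scoring & assignment** — each detection/identity pair gets the score
  `(λ_d·Cd + λ_r·Cr + λ_IoU·IoU) / (λ_d + λ_r + λ_IoU)` with default
  weights (1.0, 0.75, 1.0), where `Cd` and `Cr` are the detector and
  appearance confidences and `IoU` the overlap with that identity's
  previous box. Pairs scoring ≤ 0.5 are discarded; a Jonker–Volgenant-
  style optimal partial matching across *all* camera views then assigns
  identities, so no identity is ever duplicated within a frame and a
  weakly identified animal can inherit the one identity left over.
* **Kalman tracking** — per-identity constant-velocity filtering of the
  assigned boxes, smoothing jitter and filling short detection gaps.
* **Actigraphy** — per-frame center displacement (px), minute-binned
  actigrams, frame-level mobile/immobile classification (default cutoff
  10 px), and ROC/Youden cutoff selection (J = TPR − FPR swept over
  [0, 20] in 0.01 steps).
* **Event analytics** — class merging, per-minute prediction counts,
  5-minute moving averages, adaptive per-animal baseline thresholds
  (the smallest level suppressing all pre-treatment predictions of a
  class), bout extraction, and event-level accuracy
  `100·correct/(predicted+missed)`.
* **MOT evaluation** — MOTA, IDF1/IDP/IDR, switches, fragmentations,
  Mostly/Partially-Tracked and Mostly-Lost bands, and a per-animal
  re-identification confusion matrix.
* **Simulation** — seeded scenarios (1–3 animals, 1–2 cameras,
  rest/locomotion bouts, transits, occlusion clustering) with a
  configurable detector/classifier noise model, replacing proprietary
  footage as the test bed.

## Worked example

```python
import kennelmot as km

# simulate ~27 min of three harness-marked dogs over two camera views
scenario = km.study_scenario(duration=10_000, seed=7)
noise = km.NoiseConfig(miss_rate=0.02, jitter_sigma=2.0,
                       confusion=km.uniform_confusion(3, 0.05))
truth, detections = km.simulate_scenario(scenario, noise)

tracks = km.track_detections(detections)          # score -> assign -> Kalman
report = km.evaluate_tracks(truth.tracks, tracks)  # against ground truth
print(f"MOTA {report.mota:.3f}  IDF1 {report.idf1:.3f} "
      f"IDP {report.idp:.3f}  IDR {report.idr:.3f}  "
      f"switches {report.id_switches}")
```

prints

```
MOTA 0.980  IDF1 0.990 IDP 1.000  IDR 0.980  switches 0
```

i.e. with a 2% detector miss rate, 2 px localization jitter and 5%
identity-classifier confusion, 98% of ground-truth boxes are tracked
(`MOTA`), essentially every emitted box carries the right animal
identity (`IDP` ≈ 1), and no identity switch occurs over 10,000 frames.
The residual IDF1/IDR gap is the missed detections. Actigraphy follows
directly from the tracks:

```python
tr = tracks[0]
series = km.track_displacements(tr)                # px per analyzed frame
actigram = km.bin_activity(series, bin_duration=60.0)
labels = [km.classify_mobility(d) for d in series.values if d == d]
```

The same functionality is available from the shell:

```bash
kennelmot --seed 7 simulate --out-dir sim/ --duration 2000
kennelmot track --detections sim/dets.csv --out tracks.csv
kennelmot eval-mot --gt sim/gt.csv --pred tracks.csv --out report.json
kennelmot activity --tracks tracks.csv --bin 60 --out actigram.csv
kennelmot baseline-threshold --baseline b.csv --dosing d.csv --out filtered.csv
```

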