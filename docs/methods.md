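# Methods

`kennelmot` implements the tracking and analytics layer of an
appearance-based video-monitoring pipeline for group-housed dogs wearing
colour/reflective-pattern harnesses, decoupled from the neural networks
that produce its inputs. The package consumes per-frame detection tables
— bounding box, detector confidence `Cd`, and one appearance-classifier
confidence `Cr` per identity — and everything downstream of that point
is implemented and testable here: candidate scoring, duplicate-free
identity assignment across camera views, Kalman tracking, actigraphy,
behavior/clinical-sign analytics, and tracking evaluation.

## Candidate scoring and identity assignment

Each detection in a frame is scored against each identity:

    score = (λ_d·Cd + λ_r·Cr + λ_IoU·IoU) / (λ_d + λ_r + λ_IoU)

where `IoU` is the overlap with that identity's box on the previous
analyzed frame (0 when there is no previous box or it lives on a
different camera). The default weights are (1.0, 0.75, 1.0) and only
scores strictly above 0.5 are retained, which filters uncertain
detections before any matching happens.

Assignment is a maximum-total-score one-to-one *partial* matching over
the retained entries, pooled across all camera views of the frame — a
linear-assignment (Jonker–Volgenant-style) solve with forbidden entries
and unmatched rows/columns allowed. We implement it as an exact dynamic
program over identity subsets rather than calling a library LSA solver,
for two reasons: forbidden entries and partial matchings fall out
naturally, and the tie rules can be made exact — among equal-total
matchings the solver prefers more pairs (so a redundant confident
detection never orphans an identity) and then the lexicographically
smallest (row, column) sequence, making output fully deterministic. The
DP is O(n·2^m·m) for n detections and m identities; identity sets here
have m ≤ 3 (the harness inventory), and the implementation caps m at 20.
`scipy.optimize.linear_sum_assignment` serves as an independent
cross-check in the tests, never as the implementation.

Because the solve is global across cameras, an identity can never be
assigned twice in a frame, even on different views; and because it is
repeated from scratch every frame, errors propagate only through the
soft IoU term. A side effect the joint solve shares with the system it
models: when two of three animals are confidently identified, the third
detection can inherit the leftover identity even with an uninformative
appearance confidence, provided its score clears the threshold.

## Kalman tracking

Each identity carries an 8-dimensional constant-velocity state on
(cx, cy, w, h) with per-analyzed-frame velocities; the measurement is
the assigned box. Defaults: measurement noise σ = 2 px per coordinate
(typical localization jitter of a well-trained detector), process noise
σ = 3 px/frame² (white-noise acceleration). The process noise reflects
the maneuver statistics at the analyzed rate of 6.25 fps: a dog turning
at walking speed changes its per-frame velocity by several pixels per
frame, and a smaller value makes the filter visibly lag at direction
changes (we require < 1 px mean center error on clean streams). The
initial state has zero velocity with a variance of 100 px²/frame²
(floored independently of the measurement noise, so near-noiseless
streams still re-estimate velocity quickly) and the update uses the
Joseph form to keep covariances positive semi-definite. Width/height
estimates are clamped positive on emission.

Unassigned identities are propagated without correction for up to
`max_gap_frames` (default 12 analyzed frames ≈ 1.9 s) and emitted with
`source=filled`; past that horizon the state is retired and the
identity waits for reacquisition. When an identity reappears on a
different camera the state is re-initialized there — boxes on different
cameras live in unrelated pixel planes, so neither gap filling nor the
IoU term ever crosses views.

## Actigraphy and the mobility cutoff

Activity is the Euclidean distance in pixels between consecutive box
centers of a track (the previous *available* entry when frames are
missing; not computed across camera switches). Summing per half-open
time bin (default 60 s at fps/subsample = 25/4 analyzed fps) gives the
actigram; binning conserves total displacement exactly. Frame-level
mobility uses a strict threshold: mobile iff displacement > cutoff, with
10.0 px/frame as the shipped default. The cutoff selector sweeps the
closed grid [0, 20] in 0.01 steps and maximizes Youden's index
J = TPR − FPR (mobile positive); ties resolve to the smallest, most
sensitive cutoff. Actigram overlays across instruments use per-series
min–max normalization.

## Behavior / clinical-sign analytics

Framewise class labels (eating subclasses, drinking, ataxia, limping,
involuntary muscle movements, …, `none`) are merged (eating subclasses
recombine; ataxia+limping pool into an abnormal-gait phenotype), counted
per minute, and smoothed with a centered 5-minute moving average whose
edge windows truncate to the available neighbors (so constant series are
fixed points). We apply the moving average to the minute-binned counts
rather than to raw frame indicators; at a fixed frame rate the two are
proportional within interior windows, and minute resolution is what the
thresholding consumes.

Adaptive baseline thresholding: for each (animal, class) the threshold
is the *maximum* smoothed baseline bin — the smallest level whose
suppression removes every baseline prediction, which makes fit+apply on
the baseline itself identically zero (checked exactly in the tests).
On the treatment day, bins at or below the threshold are zeroed; bins
strictly above pass unchanged.

Events are per-class maximal label runs after closing gaps of at most 12
analyzed frames, dropping bouts under 25 frames (≈ 4 s); the merged
duration includes closed gaps. Event scoring matches predicted to truth
events greedily one-to-one, requiring the overlap to cover ≥ 50% of the
truth event; event-level accuracy is 100·correct/(predicted + missed).

## Tracking evaluation

CLEAR protocol: previous-frame correspondences persist while their IoU
stays ≥ the threshold (default 0.5, the conventional true-positive
criterion); remaining boxes are matched one-to-one over the
at-or-above-threshold pairs only, maximizing match count then total IoU.
MOTA = 1 − (misses + false positives + switches)/GT boxes; a switch is a
change of matched predicted identity between a ground-truth identity's
consecutive *matched* frames, a fragmentation a matched→lost→matched
toggle. Identity metrics use a single global trajectory-to-trajectory
min-cost matching (equivalently maximum total framewise overlap):
IDP = IDTP/(IDTP+IDFP), IDR = IDTP/(IDTP+IDFN), and IDF1 their harmonic
mean. Coverage bands: Mostly Tracked > 80% of lifespan, Mostly Lost
< 20%, Partially Tracked otherwise with both boundaries inclusive of PT.
The re-identification confusion matrix counts, per ground-truth animal,
every predicted box overlapping it at threshold (attributed to its
best-overlap animal, without one-to-one exclusivity), in percent of that
animal's frames — rows can exceed 100% when a tracker emits duplicate
identities, which the strict built-in solver never does but external
track files can. Gap-filled boxes are excluded from evaluation as
predictions by default (`include_filled` flips this), since they are
model extrapolations rather than detections.

All metrics are verified against an independently coded brute-force
reference (exhaustive per-frame matchings, permutation search over
trajectory matchings) on randomized scenarios.

## The synthetic test bed

The footage this design targets is proprietary, so the simulator
replaces it with the statistical structure the tracker assumes, *not*
with photorealism. Animals follow a two-state rest/locomotion
semi-Markov process: per-frame switch probabilities 0.02 (rest→move) and
0.05 (move→rest) give ~30 s locomotion bouts and longer rests at the
analyzed rate; locomotion speed is bout-constant, uniform in 12–30
px/frame — clearly above the 10 px mobility cutoff, as walking dogs are,
while rest is exactly stationary. Boxes (~120×95 px in a 1280×720 view)
reflect at image borders. Optional camera transits teleport a moving
animal to the adjacent view, and cluster phases (rate 0.001/frame, 150
frames) steer all animals on one camera toward a shared point,
reproducing the overlapping-box regime where occlusion errors
concentrate in real group housing.

The detector/classifier emulation mirrors the error taxonomy of such
front ends: misses (default 2%, tripled for overlapped boxes, doubled at
night), Gaussian localization jitter (2 px), duplicate boxes (1%),
Beta-distributed detector confidences (mean 0.9 by day, lower
concentration at night), and appearance confidences drawn from a
Dirichlet centered on the row of an identity-confusion matrix
(concentration 25). Class-label streams for the analytics are
background-dominated with Poisson false positives per minute on baseline
days and injected bouts — solid or sparse at a configurable
predictions-per-minute rate — on the dosing day.

What the simulator does *not* emulate: appearance itself (there are no
images, so nothing constrains the confusion matrix to resemble a real
harness classifier), correlated day-long lighting drift, box-shape
changes from posture, or social-behavior structure beyond clustering.
Passing tests therefore demonstrate that the scoring/assignment/
filtering layer is correct and robust under the assumed error
statistics; they cannot certify performance on real footage, where the
front-end error structure must be measured, not assumed.

## Problem sizes and numerical choices

The reference scenario used by `scripts/acceptance.py` and the
heaviest tests is 3 animals over 2 cameras for 10,000 analyzed frames
(≈ 27 min of video at 25/4 fps); robustness sweeps use 1,000-frame
scenarios over 10 seeds per confusion level, and the assignment oracle
runs 500 random matrices up to 4×3. These sizes keep the whole suite in
the low tens of seconds while leaving the measured rates stable to well
under a percentage point across seeds.

Degenerate inputs are rejected rather than coerced: non-positive box
extents, confidences outside [0, 1], mixed frame indices in one matrix,
single-class label sets in the ROC sweep, empty ground truth in the
evaluator. Exact float equality is used only where both sides are
computed from identical sums (the assignment DP vs its reconstruction);
everywhere else comparisons carry explicit tolerances.

## Known limitations

* The assignment is strictly one-to-one per frame; systems that solve
  per camera can emit the same identity twice across views, and the
  confusion-matrix evaluator accounts for such double IDs even though
  the built-in solver cannot produce them.
* The constant-velocity model has no notion of walls or gait; filled
  boxes extrapolate straight lines and degrade with gap length.
* The mobility cutoff is resolution- and viewpoint-dependent; 10 px at
  one camera geometry is not transferable without re-running the ROC
  sweep on matched ground truth.
* Minute-level smoothing before thresholding trades sensitivity to very
  short clinical events for suppression of isolated false positives;
  events shorter than the window are attenuated ~proportionally.
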