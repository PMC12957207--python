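"""Scenario simulator: ground-truth trajectories and noisy detection streams.

The footage this toolkit was designed around (group-housed dogs filmed
front-view from one or two adjacent kennel cameras) is proprietary, so
the test bed is simulated with the statistical structure the tracker
assumes:

* 1-3 animals per scenario, each alternating between *rest* bouts (zero
  velocity — the immobile ground truth) and *locomotion* bouts with a
  bout-constant speed and smoothly wandering heading (mobile), staying
  inside the image; optional transits move an animal to the adjacent
  camera view; occasional *cluster* phases attract all animals on one
  camera to a shared point, producing the overlapping-box regime where
  occlusion errors concentrate.
* The detector/classifier front end is emulated per truth box: misses
  (optionally amplified at night and under box overlap), Gaussian
  localization jitter, Beta-distributed detector confidences, duplicate
  boxes, and per-identity appearance confidences drawn from a Dirichlet
  centered on the row of an identity-confusion matrix.
* Behavior/clinical-sign label streams for the analytics modules:
  baseline days carry only sparse false-positive frames; a dosing day
  additionally carries injected class bouts.

Everything is seeded and reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .core import (
    DEFAULT_IDENTITIES,
    BoundingBox,
    Detection,
    Track,
    TrackEntry,
    ValidationError,
    validate_identity_set,
)
from .events import BACKGROUND, DEFAULT_LABEL_SET, ClassSeries, frames_per_minute
from .geometry import iou

__all__ = [
    "ScenarioConfig",
    "NoiseConfig",
    "GroundTruth",
    "uniform_confusion",
    "generate_truth",
    "emulate_detections",
    "emulate_class_series",
    "simulate_scenario",
    "study_scenario",
]


@dataclass(frozen=True)
class ScenarioConfig:
    """Ground-truth scenario parameters.

    Speeds are pixels per analyzed frame; with the default 10 px mobility
    cutoff, the locomotion speed range (12-30 px/frame) and resting
    stillness put the two mobility classes clearly on either side of the
    cutoff, as walking vs resting animals are in real footage.
    """

    n_animals: int = 3
    identities: tuple[str, ...] = DEFAULT_IDENTITIES
    n_cameras: int = 2
    image_size: tuple[int, int] = (1280, 720)  # (width, height) px
    duration: int = 2000                        # analyzed frames
    p_start_move: float = 0.02                  # rest -> locomotion, per frame
    p_stop_move: float = 0.05                   # locomotion -> rest, per frame
    speed_range: tuple[float, float] = (12.0, 30.0)  # px/frame while moving
    heading_jitter: float = 0.3                 # rad/frame
    transit_prob: float = 0.0                   # camera switch per moving frame
    cluster_rate: float = 0.0                   # cluster-phase onset per frame
    cluster_duration: int = 150                 # frames per cluster phase
    box_size: tuple[float, float] = (120.0, 95.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if not (1 <= self.n_animals <= len(self.identities)):
            raise ValidationError(
                f"n_animals={self.n_animals} exceeds the {len(self.identities)} identities"
            )
        if self.n_cameras < 1:
            raise ValidationError("need at least one camera")
        if self.speed_range[0] < 0 or self.speed_range[1] < self.speed_range[0]:
            raise ValidationError(f"bad speed range {self.speed_range}")
        if self.duration < 1:
            raise ValidationError("duration must be >= 1 frame")


def uniform_confusion(n: int, off_diagonal: float) -> np.ndarray:
    """Row-stochastic confusion matrix with uniform off-diagonal mass."""
    if not (0.0 <= off_diagonal <= 1.0):
        raise ValidationError("off-diagonal mass must lie in [0, 1]")
    if n == 1:
        return np.ones((1, 1))
    m = np.full((n, n), off_diagonal / (n - 1))
    np.fill_diagonal(m, 1.0 - off_diagonal)
    return m


@dataclass(frozen=True)
class NoiseConfig:
    """Detector/classifier error model applied to ground-truth boxes."""

    miss_rate: float = 0.02
    duplicate_rate: float = 0.01
    jitter_sigma: float = 2.0           # px, on box corners and extents
    det_conf_mean: float = 0.9
    det_conf_concentration: float = 30.0
    confusion: np.ndarray | None = None  # identity x identity, row-stochastic
    id_conf_concentration: float = 25.0  # Dirichlet concentration around the row
    night: bool = False
    night_factor: float = 2.0            # multiplies miss rate and confusion
    occlusion_miss_factor: float = 3.0   # multiplies miss rate for overlapped boxes

    def __post_init__(self) -> None:
        for name in ("miss_rate", "duplicate_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValidationError(f"{name} must lie in [0, 1], got {v}")
        if self.confusion is not None:
            m = np.asarray(self.confusion, float)
            if m.ndim != 2 or m.shape[0] != m.shape[1]:
                raise ValidationError("confusion matrix must be square")
            if np.any(m < 0) or not np.allclose(m.sum(axis=1), 1.0):
                raise ValidationError("confusion rows must be non-negative and sum to 1")


@dataclass
class GroundTruth:
    """Simulated truth: per-identity tracks plus framewise mobility labels."""

    tracks: list[Track]
    mobility: dict[str, np.ndarray]  # identity -> bool array, True = mobile
    config: ScenarioConfig


def _clamp(v: float, lo: float, hi: float) -> float:
    return min(max(v, lo), hi)


def generate_truth(config: ScenarioConfig) -> GroundTruth:
    """Simulate seeded rest/locomotion trajectories inside the image."""
    rng = np.random.default_rng(config.seed)
    W, H = config.image_size
    identities = validate_identity_set(config.identities)[: config.n_animals]
    bw0, bh0 = config.box_size

    tracks = [Track(ident) for ident in identities]
    mobility = {ident: np.zeros(config.duration, bool) for ident in identities}

    # per-animal state
    size = [(bw0 * rng.uniform(0.9, 1.1), bh0 * rng.uniform(0.9, 1.1))
            for _ in identities]
    camera = [int(rng.integers(config.n_cameras)) for _ in identities]
    pos = []
    for i in range(config.n_animals):
        bw, bh = size[i]
        pos.append([rng.uniform(bw / 2, W - bw / 2), rng.uniform(bh / 2, H - bh / 2)])
    moving = [False] * config.n_animals
    speed = [0.0] * config.n_animals
    heading = [rng.uniform(0, 2 * math.pi) for _ in identities]

    cluster_left = 0
    cluster_point = (0.0, 0.0)
    cluster_cam = 0

    for t in range(config.duration):
        if cluster_left > 0:
            cluster_left -= 1
        elif config.cluster_rate > 0 and rng.random() < config.cluster_rate:
            cluster_left = config.cluster_duration
            cluster_cam = int(rng.integers(config.n_cameras))
            cluster_point = (rng.uniform(0.25 * W, 0.75 * W),
                             rng.uniform(0.25 * H, 0.75 * H))

        for i, ident in enumerate(identities):
            bw, bh = size[i]
            if moving[i]:
                if rng.random() < config.p_stop_move:
                    moving[i] = False
            elif rng.random() < config.p_start_move:
                moving[i] = True
                speed[i] = rng.uniform(*config.speed_range)
                heading[i] = rng.uniform(0, 2 * math.pi)

            if moving[i]:
                if cluster_left > 0 and camera[i] == cluster_cam:
                    # steer toward the shared attractor during cluster phases
                    dx = cluster_point[0] - pos[i][0]
                    dy = cluster_point[1] - pos[i][1]
                    if math.hypot(dx, dy) > speed[i]:
                        heading[i] = math.atan2(dy, dx) + rng.normal(0, 0.1)
                    else:
                        heading[i] = rng.uniform(0, 2 * math.pi)
                else:
                    heading[i] += rng.normal(0, config.heading_jitter)
                if config.n_cameras > 1 and rng.random() < config.transit_prob:
                    camera[i] = int(rng.integers(config.n_cameras))
                    pos[i] = [rng.uniform(bw / 2, W - bw / 2),
                              rng.uniform(bh / 2, H - bh / 2)]
                else:
                    nx = pos[i][0] + speed[i] * math.cos(heading[i])
                    ny = pos[i][1] + speed[i] * math.sin(heading[i])
                    if nx < bw / 2 or nx > W - bw / 2:
                        heading[i] = math.pi - heading[i]
                        nx = _clamp(nx, bw / 2, W - bw / 2)
                    if ny < bh / 2 or ny > H - bh / 2:
                        heading[i] = -heading[i]
                        ny = _clamp(ny, bh / 2, H - bh / 2)
                    pos[i] = [nx, ny]
                mobility[ident][t] = True

            box = BoundingBox(pos[i][0] - bw / 2, pos[i][1] - bh / 2, bw, bh)
            tracks[i].append(TrackEntry(t, f"cam{camera[i]}", box, "observed"))

    return GroundTruth(tracks, mobility, config)


def _jitter_box(box: BoundingBox, sigma: float, rng: np.random.Generator) -> BoundingBox:
    if sigma == 0:
        return box
    w = max(box.width + rng.normal(0, sigma), 1.0)
    h = max(box.height + rng.normal(0, sigma), 1.0)
    return BoundingBox(box.x + rng.normal(0, sigma), box.y + rng.normal(0, sigma), w, h)


def emulate_detections(
    truth: GroundTruth,
    noise: NoiseConfig | None = None,
    seed: int = 0,
) -> list[Detection]:
    """Turn ground-truth boxes into a noisy detection stream.

    Each truth box is emitted with probability ``1 - miss_rate`` (the rate
    scaled up at night and when the box overlaps another animal on the
    same camera), localization-jittered, given a Beta detector confidence
    and a Dirichlet appearance-confidence row centered on its identity's
    confusion-matrix row; duplicates are added at ``duplicate_rate``.
    """
    noise = noise if noise is not None else NoiseConfig()
    rng = np.random.default_rng(seed)
    identities = tuple(tr.identity for tr in truth.tracks)
    n_id = len(truth.config.identities)
    confusion = (
        np.asarray(noise.confusion, float)
        if noise.confusion is not None
        else np.eye(n_id)
    )
    if confusion.shape != (n_id, n_id):
        raise ValidationError(
            f"confusion matrix shape {confusion.shape} does not match "
            f"{n_id} identities"
        )
    if noise.night:
        off = confusion - np.diag(np.diag(confusion))
        off = off * noise.night_factor
        confusion = off + np.diag(1.0 - off.sum(axis=1))
        if np.any(np.diag(confusion) < 0):
            raise ValidationError("night_factor pushes confusion rows past 1")

    mean = noise.det_conf_mean
    conc = noise.det_conf_concentration
    beta_a, beta_b = mean * conc, (1.0 - mean) * conc

    # index truth boxes per frame for the occlusion check
    by_frame: dict[int, list[tuple[int, TrackEntry]]] = {}
    for i, tr in enumerate(truth.tracks):
        for e in tr.entries:
            by_frame.setdefault(e.frame, []).append((i, e))

    all_ids = tuple(truth.config.identities)
    detections: list[Detection] = []
    for frame in sorted(by_frame):
        entries = by_frame[frame]
        for i, e in entries:
            miss = noise.miss_rate
            if noise.night:
                miss *= noise.night_factor
            overlapped = any(
                j != i and o.camera_id == e.camera_id and iou(o.box, e.box) > 0.1
                for j, o in entries
            )
            if overlapped:
                miss *= noise.occlusion_miss_factor
            if rng.random() < min(miss, 1.0):
                continue
            n_copies = 1 + (rng.random() < noise.duplicate_rate)
            row = confusion[all_ids.index(identities[i])]
            for _ in range(n_copies):
                box = _jitter_box(e.box, noise.jitter_sigma, rng)
                det_conf = float(rng.beta(beta_a, beta_b)) if conc > 0 else mean
                alphas = noise.id_conf_concentration * row
                gammas = np.array([rng.gamma(a) if a > 0 else 0.0 for a in alphas])
                total = gammas.sum()
                conf = gammas / total if total > 0 else row
                id_conf = {ident: float(c) for ident, c in zip(all_ids, conf)}
                detections.append(
                    Detection(e.camera_id, frame, box, det_conf, id_conf)
                )
    return detections


def emulate_class_series(
    identity: str,
    n_minutes: int = 60,
    fp_rate: float = 0.5,
    bouts: Sequence[tuple[str, float, float]] = (),
    label_set: tuple[str, ...] = DEFAULT_LABEL_SET,
    fp_classes: Sequence[str] | None = None,
    bout_rate: float | None = None,
    fps: float = 25.0,
    subsample: int = 4,
    seed: int = 0,
) -> ClassSeries:
    """Bout-structured class-label series for one animal.

    ``fp_rate`` is the expected number of spurious (false-positive) frames
    per minute, each a random non-background class scattered uniformly —
    the classifier noise floor observed on baseline days.  ``bouts`` is a
    list of (class, start_minute, duration_minutes) injections emulating
    genuine signals on a dosing day; bout frames are never overwritten by
    false positives.  ``bout_rate`` makes injections sparse: instead of
    labeling every frame, bout minutes receive on average that many
    predictions per minute (a weak but persistent signal).
    """
    rng = np.random.default_rng(seed)
    fpm = frames_per_minute(fps, subsample)
    n_frames = int(round(n_minutes * fpm))
    labels = np.full(n_frames, BACKGROUND, dtype=object)

    for cls, start_min, dur_min in bouts:
        if cls not in label_set:
            raise ValidationError(f"bout class {cls!r} outside the label set")
        a = int(round(start_min * fpm))
        b = min(int(round((start_min + dur_min) * fpm)), n_frames)
        if bout_rate is None:
            labels[a:b] = cls
        else:
            for minute_start in range(a, b, int(round(fpm))):
                hi = min(minute_start + int(round(fpm)), b)
                k = rng.poisson(bout_rate)
                for f in rng.integers(minute_start, hi, size=k):
                    labels[f] = cls

    pool = tuple(fp_classes) if fp_classes is not None else tuple(
        c for c in label_set if c != BACKGROUND
    )
    if fp_rate > 0 and pool:
        for minute in range(n_minutes):
            k = rng.poisson(fp_rate)
            if k == 0:
                continue
            lo, hi = int(round(minute * fpm)), min(int(round((minute + 1) * fpm)), n_frames)
            frames = rng.integers(lo, hi, size=k)
            for f in frames:
                if labels[f] == BACKGROUND:
                    labels[f] = pool[rng.integers(len(pool))]
    return ClassSeries(identity, labels, label_set)


def study_scenario(
    duration: int = 10_000, seed: int = 7, n_cameras: int = 2
) -> ScenarioConfig:
    """The reference study conditions: three harness-marked animals over
    adjacent camera views with occasional transits and cluster phases."""
    return ScenarioConfig(
        n_animals=3,
        n_cameras=n_cameras,
        duration=duration,
        transit_prob=0.0005 if n_cameras > 1 else 0.0,
        cluster_rate=0.001,
        seed=seed,
    )


def simulate_scenario(
    scenario: ScenarioConfig,
    noise: NoiseConfig | None = None,
    detection_seed: int | None = None,
) -> tuple[GroundTruth, list[Detection]]:
    """Generate truth and its emulated detection stream in one call."""
    truth = generate_truth(scenario)
    seed = detection_seed if detection_seed is not None else scenario.seed + 1
    return truth, emulate_detections(truth, noise, seed)
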