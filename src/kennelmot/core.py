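"""Shared domain types for the tracking and analytics layers.

The toolkit operates downstream of a per-frame animal detector and an
appearance (harness) classifier: its unit of input is a :class:`Detection`
carrying a bounding box, a detector confidence ``Cd`` and one appearance
confidence ``Cr`` per candidate identity.  Identities are persistent animal
labels — by default the three harness patterns used for group-housed dogs
(red/no-reflector, yellow/stripes, black/squares).

All coordinates are image pixels with the origin at the top-left corner,
x growing rightward and y downward.  Frame indices count *analyzed* frames:
when the upstream pipeline subsamples the camera stream (default every 4th
frame of a 25 fps feed), index ``t`` corresponds to wall-clock time
``t * subsample / fps`` seconds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, replace
from typing import Iterable, Iterator, Mapping, Sequence

__all__ = [
    "DEFAULT_IDENTITIES",
    "BoundingBox",
    "Detection",
    "TrackerConfig",
    "AssignedPair",
    "FrameAssignment",
    "TrackEntry",
    "Track",
    "ValidationError",
    "validate_identity_set",
]

#: Default identity labels: harness colour / night-reflective pattern.
DEFAULT_IDENTITIES: tuple[str, ...] = ("R-N", "Y-St", "B-Sq")


class ValidationError(ValueError):
    """Raised when an input violates a documented invariant."""


def validate_identity_set(identities: Sequence[str]) -> tuple[str, ...]:
    """Check an identity label list (unique, non-empty) and freeze it."""
    ids = tuple(identities)
    if len(ids) == 0:
        raise ValidationError("identity set must contain at least one label")
    if len(set(ids)) != len(ids):
        raise ValidationError(f"identity labels must be unique, got {ids}")
    return ids


@dataclass(frozen=True)
class BoundingBox:
    """Axis-aligned box stored as (x_left, y_top, width, height) in pixels."""

    x: float
    y: float
    width: float
    height: float

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not math.isfinite(v):
                raise ValidationError(f"box {f.name} must be finite, got {v}")
        if self.width <= 0 or self.height <= 0:
            raise ValidationError(
                f"box extents must be positive, got {self.width}x{self.height}"
            )

    @property
    def center(self) -> tuple[float, float]:
        return (self.x + self.width / 2.0, self.y + self.height / 2.0)

    @property
    def area(self) -> float:
        return self.width * self.height

    def translated(self, dx: float, dy: float) -> "BoundingBox":
        return replace(self, x=self.x + dx, y=self.y + dy)


def _check_conf(name: str, value: float) -> float:
    v = float(value)
    if not (0.0 <= v <= 1.0) or not math.isfinite(v):
        raise ValidationError(f"{name} must lie in [0, 1], got {value}")
    return v


@dataclass(frozen=True)
class Detection:
    """One candidate detection on one camera at one analyzed frame.

    ``det_conf`` (Cd) is the detector confidence; ``id_conf`` maps every
    identity in the configured set to its appearance-classifier confidence
    (Cr).  Both live in [0, 1].
    """

    camera_id: str
    frame: int
    box: BoundingBox
    det_conf: float
    id_conf: Mapping[str, float]

    def __post_init__(self) -> None:
        if self.frame < 0:
            raise ValidationError(f"frame index must be >= 0, got {self.frame}")
        _check_conf("det_conf", self.det_conf)
        for ident, c in self.id_conf.items():
            _check_conf(f"id_conf[{ident!r}]", c)

    def validate_identities(self, identities: Sequence[str]) -> None:
        if set(self.id_conf) != set(identities):
            raise ValidationError(
                f"id_conf keys {sorted(self.id_conf)} do not match the "
                f"identity set {sorted(identities)}"
            )


@dataclass(frozen=True)
class TrackerConfig:
    """Tracker parameters.

    The score weights and thresholds default to the published operating
    point of the system this toolkit models: score weights
    (lambda_d, lambda_r, lambda_iou) = (1.0, 0.75, 1.0), candidate scores
    retained only when > 0.5, a 10 px/frame mobile/immobile cutoff, and a
    subsample factor of 4 on a 25 fps stream.
    """

    lambda_d: float = 1.0
    lambda_r: float = 0.75
    lambda_iou: float = 1.0
    score_threshold: float = 0.5
    max_gap_frames: int = 12
    subsample: int = 4
    fps: float = 25.0
    process_noise: float = 3.0      # px/frame^2 acceleration noise per coordinate
    measurement_noise: float = 2.0  # px, per measured coordinate
    mobility_cutoff: float = 10.0   # px per analyzed frame

    def __post_init__(self) -> None:
        weights = (self.lambda_d, self.lambda_r, self.lambda_iou)
        if any(w < 0 for w in weights):
            raise ValidationError(f"score weights must be >= 0, got {weights}")
        if sum(weights) <= 0:
            raise ValidationError("score weights must have a positive sum")
        if not (0.0 <= self.score_threshold <= 1.0):
            raise ValidationError(
                f"score_threshold must lie in [0, 1], got {self.score_threshold}"
            )
        if self.max_gap_frames < 0:
            raise ValidationError("max_gap_frames must be >= 0")
        if self.subsample < 1:
            raise ValidationError("subsample must be >= 1")
        if self.fps <= 0:
            raise ValidationError("fps must be positive")
        if self.process_noise < 0 or self.measurement_noise < 0:
            raise ValidationError("noise scales must be >= 0")
        if self.mobility_cutoff < 0:
            raise ValidationError("mobility_cutoff must be >= 0")

    @property
    def analyzed_fps(self) -> float:
        """Frame rate of the analyzed (subsampled) stream."""
        return self.fps / self.subsample

    @property
    def weight_sum(self) -> float:
        return self.lambda_d + self.lambda_r + self.lambda_iou


@dataclass(frozen=True)
class AssignedPair:
    """One identity->detection pairing chosen by the assignment solver."""

    detection: Detection
    score: float


@dataclass
class FrameAssignment:
    """Duplicate-free identity->detection mapping for one analyzed frame.

    Each identity appears at most once and each detection is used at most
    once, pooled across every camera view.
    """

    frame: int
    pairs: dict[str, AssignedPair] = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen: set[int] = set()
        for pair in self.pairs.values():
            key = id(pair.detection)
            if key in seen:
                raise ValidationError("a detection is assigned to two identities")
            seen.add(key)

    def total(self) -> float:
        """Sum of the stored candidate scores (the solver's objective)."""
        return float(sum(p.score for p in self.pairs.values()))

    def identities(self) -> tuple[str, ...]:
        return tuple(self.pairs)

    def __len__(self) -> int:
        return len(self.pairs)

    def __contains__(self, identity: str) -> bool:
        return identity in self.pairs


@dataclass(frozen=True)
class TrackEntry:
    """One time step of a track: an observed (smoothed) or gap-filled box."""

    frame: int
    camera_id: str
    box: BoundingBox
    source: str  # "observed" | "filled"

    def __post_init__(self) -> None:
        if self.source not in ("observed", "filled"):
            raise ValidationError(f"unknown entry source {self.source!r}")


@dataclass
class Track:
    """Per-identity time series of boxes with provenance."""

    identity: str
    entries: list[TrackEntry] = field(default_factory=list)

    def append(self, entry: TrackEntry) -> None:
        if self.entries and entry.frame <= self.entries[-1].frame:
            raise ValidationError(
                f"track {self.identity}: frame {entry.frame} does not increase "
                f"past {self.entries[-1].frame}"
            )
        self.entries.append(entry)

    def frames(self) -> list[int]:
        return [e.frame for e in self.entries]

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self) -> Iterator[TrackEntry]:
        return iter(self.entries)

    def validate(self, max_gap_frames: int | None = None) -> None:
        """Check monotone frames and, optionally, bounded filled runs."""
        prev = None
        run = 0
        for e in self.entries:
            if prev is not None and e.frame <= prev:
                raise ValidationError(f"track {self.identity}: frames not increasing")
            prev = e.frame
            run = run + 1 if e.source == "filled" else 0
            if max_gap_frames is not None and run > max_gap_frames:
                raise ValidationError(
                    f"track {self.identity}: filled run exceeds {max_gap_frames}"
                )


def group_by_frame(detections: Iterable[Detection]) -> list[tuple[int, list[Detection]]]:
    """Group detections (any camera order) into per-frame lists, sorted by frame."""
    by_frame: dict[int, list[Detection]] = {}
    for det in detections:
        by_frame.setdefault(det.frame, []).append(det)
    return sorted(by_frame.items())
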