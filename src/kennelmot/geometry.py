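"""Box geometry and the weighted candidate score.

The candidate score fuses three confidence signals for pairing a detection
with an identity::

    score = (lambda_d * Cd + lambda_r * Cr + lambda_iou * IoU)
            / (lambda_d + lambda_r + lambda_iou)

where ``Cd`` is the detector confidence, ``Cr`` the appearance-classifier
confidence for that identity, and ``IoU`` the overlap between the candidate
box and the identity's box in the previous analyzed frame (0 when there is
no previous box, or the previous box lives on a different camera).  The
default weights are (1.0, 0.75, 1.0); the convex combination keeps the
score in [0, 1].
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .core import BoundingBox, Detection, TrackerConfig, ValidationError

__all__ = ["iou", "center", "displacement", "candidate_score", "ScoredCandidate"]


def iou(a: BoundingBox, b: BoundingBox) -> float:
    """Intersection-over-union of two boxes; 0 when disjoint, 1 iff identical."""
    ix = min(a.x + a.width, b.x + b.width) - max(a.x, b.x)
    iy = min(a.y + a.height, b.y + b.height) - max(a.y, b.y)
    if ix <= 0.0 or iy <= 0.0:
        return 0.0
    inter = ix * iy
    # corner-difference rounding can push inter past the true area; clamp
    return min(inter / (a.area + b.area - inter), 1.0)


def center(box: BoundingBox) -> tuple[float, float]:
    """Box center (x_left + w/2, y_top + h/2)."""
    return box.center


def displacement(prev_box: BoundingBox, cur_box: BoundingBox) -> float:
    """Euclidean distance in pixels between the two box centers."""
    (px, py), (cx, cy) = prev_box.center, cur_box.center
    return math.hypot(cx - px, cy - py)


def _check_unit(name: str, v: float) -> float:
    if not (0.0 <= v <= 1.0) or not math.isfinite(v):
        raise ValidationError(f"{name} must lie in [0, 1], got {v}")
    return float(v)


def candidate_score(
    cd: float, cr: float, iou_prev: float, config: TrackerConfig | None = None
) -> float:
    """Weighted mean of (Cd, Cr, IoU-with-previous-box); lies in [0, 1]."""
    cfg = config if config is not None else TrackerConfig()
    _check_unit("cd", cd)
    _check_unit("cr", cr)
    _check_unit("iou_prev", iou_prev)
    num = cfg.lambda_d * cd + cfg.lambda_r * cr + cfg.lambda_iou * iou_prev
    return num / cfg.weight_sum


@dataclass(frozen=True)
class ScoredCandidate:
    """A (detection, identity) pairing with its IoU context and score."""

    detection: Detection
    identity: str
    iou_prev: float
    score: float
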