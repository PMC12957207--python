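"""Duplicate-free identity assignment for one analyzed frame.

Detections from every camera view of a frame are pooled into a single
score matrix (rows = detections, columns = identities).  Entries are the
weighted candidate scores; entries at or below the retention threshold
(default 0.5) are excluded outright, which filters uncertain detections
and caps the false-positive rate.  The solver then picks the one-to-one
partial matching over the retained entries that maximizes the summed
score — the linear-assignment step of the tracking strategy, equivalent
to a Jonker–Volgenant solve with forbidden entries and unmatched rows
and columns allowed.

Because the matrix spans all cameras, the same identity can never be
assigned twice within a frame, even to boxes on different views; and
because the solve is repeated from scratch every frame, a wrong pairing
on one frame carries over only through the (soft) IoU term, never as a
hard constraint.  The joint solve is also what lets a low-confidence
detection inherit the one identity left over after its confident
cage-mates are placed.

Exact tie handling: among equal-total matchings the solver prefers more
pairs, then the lexicographically smallest (row, column) pair sequence,
so output is deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import (
    AssignedPair,
    BoundingBox,
    Detection,
    FrameAssignment,
    TrackerConfig,
    ValidationError,
)
from .geometry import candidate_score, iou

__all__ = ["ScoreMatrix", "build_score_matrix", "assign_ids", "assignment_total"]

# Bitmask DP over identities; ample for harness-style identity sets (<= 3).
_MAX_IDENTITIES = 20


@dataclass
class ScoreMatrix:
    """Candidate scores for one frame; NaN marks excluded entries."""

    frame: int
    detections: list[Detection]
    identities: tuple[str, ...]
    scores: np.ndarray   # (n_detections, n_identities); NaN = excluded
    iou_prev: np.ndarray  # same shape; 0 where no usable previous box

    @property
    def retained(self) -> np.ndarray:
        return ~np.isnan(self.scores)

    def __post_init__(self) -> None:
        if self.scores.shape != (len(self.detections), len(self.identities)):
            raise ValidationError("score matrix shape mismatch")


PrevBoxes = dict[str, tuple[str, BoundingBox]]


def build_score_matrix(
    detections: list[Detection],
    previous: PrevBoxes | FrameAssignment | None,
    config: TrackerConfig | None = None,
    identities: tuple[str, ...] | None = None,
) -> ScoreMatrix:
    """Score every (detection, identity) pair of one frame across all cameras.

    ``previous`` supplies each identity's box in the previous analyzed frame
    (observed or gap-filled) together with its camera; the IoU term is zero
    for identities without one, or whose previous box is on a different
    camera than the candidate detection.
    """
    cfg = config if config is not None else TrackerConfig()
    if detections:
        frames = {d.frame for d in detections}
        if len(frames) > 1:
            raise ValidationError(f"detections span multiple frames: {sorted(frames)}")
        frame = detections[0].frame
    else:
        frame = -1

    if identities is None:
        identities = tuple(detections[0].id_conf) if detections else ()
    for det in detections:
        det.validate_identities(identities)

    prev: PrevBoxes = {}
    if isinstance(previous, FrameAssignment):
        prev = {
            ident: (p.detection.camera_id, p.detection.box)
            for ident, p in previous.pairs.items()
        }
    elif previous:
        prev = dict(previous)

    n, m = len(detections), len(identities)
    scores = np.full((n, m), np.nan)
    ious = np.zeros((n, m))
    for r, det in enumerate(detections):
        for c, ident in enumerate(identities):
            prior = prev.get(ident)
            if prior is not None and prior[0] == det.camera_id:
                ious[r, c] = iou(prior[1], det.box)
            s = candidate_score(det.det_conf, det.id_conf[ident], ious[r, c], cfg)
            if s > cfg.score_threshold:
                scores[r, c] = s
    return ScoreMatrix(frame, list(detections), identities, scores, ious)


def assign_ids(matrix: ScoreMatrix) -> FrameAssignment:
    """Maximum-total-score duplicate-free partial matching of the matrix.

    Exact dynamic program over identity subsets: maximizes total score,
    then pair count, then prefers the lexicographically smallest
    (row, column) pair sequence.  Unmatched detections and identities are
    simply left out; an empty assignment is a valid result.
    """
    n, m = matrix.scores.shape
    if m > _MAX_IDENTITIES:
        raise ValidationError(f"more than {_MAX_IDENTITIES} identities unsupported")

    scores = matrix.scores
    full = (1 << m) - 1
    # best[i][mask]: (total, pairs) achievable from row i with free-identity mask
    best = [[(0.0, 0)] * (1 << m) for _ in range(n + 1)]
    for i in range(n - 1, -1, -1):
        row = scores[i]
        for mask in range(1 << m):
            cand = best[i + 1][mask]
            for c in range(m):
                bit = 1 << c
                if mask & bit and not np.isnan(row[c]):
                    t, p = best[i + 1][mask ^ bit]
                    option = (row[c] + t, p + 1)
                    if option > cand:
                        cand = option
            best[i][mask] = cand

    pairs: dict[str, AssignedPair] = {}
    mask = full
    for i in range(n):
        target = best[i][mask]
        chosen = None
        # prefer matching this row (earlier rows matched sort first), smallest column
        for c in range(m):
            bit = 1 << c
            if mask & bit and not np.isnan(scores[i, c]):
                t, p = best[i + 1][mask ^ bit]
                if (scores[i, c] + t, p + 1) == target:
                    chosen = c
                    break
        if chosen is not None:
            ident = matrix.identities[chosen]
            pairs[ident] = AssignedPair(matrix.detections[i], float(scores[i, chosen]))
            mask ^= 1 << chosen
    return FrameAssignment(matrix.frame, pairs)


def assignment_total(assignment: FrameAssignment) -> float:
    """Sum of assigned candidate scores (the solver's objective value)."""
    return assignment.total()
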