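"""Multi-object-tracking evaluation: CLEAR metrics, identity metrics, bands.

Given ground-truth tracks and predicted tracks over the same frames (and
cameras), this module computes:

* CLEAR-MOT error counts and MOTA = 1 - (misses + FP + switches) / #GT
  boxes, with the standard correspondence protocol: previous-frame
  matches persist while their IoU stays at or above the threshold, and
  remaining boxes are re-matched with a maximum-IoU one-to-one solve.
* Identity metrics IDP / IDR / IDF1 under a single global min-cost
  matching between ground-truth and predicted trajectories: IDTP counts
  frames where the matched pair overlaps (IoU >= threshold), and
  IDP = IDTP/(IDTP+IDFP), IDR = IDTP/(IDTP+IDFN),
  IDF1 = 2*IDTP/(2*IDTP+IDFP+IDFN) — the harmonic mean of IDP and IDR.
* Track-coverage bands: Mostly Tracked (> 80% of lifespan matched),
  Mostly Lost (< 20%), Partially Tracked otherwise (bounds inclusive of
  PT).
* A re-identification confusion matrix in row percent, where every
  predicted box overlapping a ground-truth box counts — so rows can
  exceed 100% when a tracker emits duplicate identities for one animal.

A ground-truth box can only match predictions on its own camera.  The
IoU acceptance threshold defaults to 0.5, the conventional true-positive
criterion.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment

from .core import BoundingBox, Track, ValidationError
from .geometry import iou

__all__ = [
    "MOTReport",
    "frame_match",
    "compute_clear_mot",
    "compute_id_metrics",
    "coverage_bands",
    "reid_confusion",
    "evaluate_tracks",
]

# (identity -> (camera_id, box)) per frame
FrameBoxes = dict[str, tuple[str, BoundingBox]]


@dataclass
class MOTReport:
    mota: float
    idf1: float
    idp: float
    idr: float
    misses: int
    false_positives: int
    id_switches: int
    fragmentations: int
    mostly_tracked: int
    partially_tracked: int
    mostly_lost: int
    num_gt_boxes: int
    reid_confusion: dict[str, dict[str, float]] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "mota": self.mota,
            "idf1": self.idf1,
            "idp": self.idp,
            "idr": self.idr,
            "misses": self.misses,
            "false_positives": self.false_positives,
            "id_switches": self.id_switches,
            "fragmentations": self.fragmentations,
            "mostly_tracked": self.mostly_tracked,
            "partially_tracked": self.partially_tracked,
            "mostly_lost": self.mostly_lost,
            "num_gt_boxes": self.num_gt_boxes,
            "reid_confusion": self.reid_confusion,
        }


def _tracks_by_frame(
    tracks: list[Track], include_filled: bool = True
) -> dict[int, FrameBoxes]:
    frames: dict[int, FrameBoxes] = {}
    for tr in tracks:
        for e in tr.entries:
            if not include_filled and e.source == "filled":
                continue
            frames.setdefault(e.frame, {})[tr.identity] = (e.camera_id, e.box)
    return frames


def _iou_same_camera(a: tuple[str, BoundingBox], b: tuple[str, BoundingBox]) -> float:
    return iou(a[1], b[1]) if a[0] == b[0] else 0.0


def frame_match(
    gt: FrameBoxes,
    pred: FrameBoxes,
    iou_threshold: float = 0.5,
    persistent: dict[str, str] | None = None,
) -> dict[str, str]:
    """One-to-one max-IoU correspondence for a single frame.

    ``persistent`` carries previous-frame (gt -> pred) pairs, which are
    kept while both boxes are present and still overlap at the threshold
    (the CLEAR protocol); the remaining boxes are matched one-to-one over
    the pairs at or above the threshold only, maximizing the number of
    matches and, among those, the total IoU.
    """
    matches: dict[str, str] = {}
    taken: set[str] = set()
    if persistent:
        for g, p in persistent.items():
            if g in gt and p in pred and _iou_same_camera(gt[g], pred[p]) >= iou_threshold:
                matches[g] = p
                taken.add(p)
    g_free = [g for g in gt if g not in matches]
    p_free = [p for p in pred if p not in taken]
    if g_free and p_free:
        mat = np.array(
            [[_iou_same_camera(gt[g], pred[p]) for p in p_free] for g in g_free]
        )
        # below-threshold pairs are not candidates; the large negative value
        # makes the solver take every achievable valid pair first
        gain = np.where(mat >= iou_threshold, mat, -1e6)
        rows, cols = linear_sum_assignment(-gain)
        for r, c in zip(rows, cols):
            if mat[r, c] >= iou_threshold:
                matches[g_free[r]] = p_free[c]
    return matches


def compute_clear_mot(
    gt_frames: dict[int, FrameBoxes],
    pred_frames: dict[int, FrameBoxes],
    iou_threshold: float = 0.5,
) -> dict:
    """CLEAR-MOT error counts and MOTA over a frame-indexed scenario.

    An identity switch is counted when a ground-truth identity's matched
    predicted identity differs from the one on its previous *matched*
    frame; a fragmentation whenever its matched status toggles
    matched -> unmatched -> matched.
    """
    num_gt = sum(len(b) for b in gt_frames.values())
    if num_gt == 0:
        raise ValidationError("empty ground truth")
    misses = fp = switches = frag = 0
    last_pred: dict[str, str] = {}      # gt identity -> last matched pred identity
    prev_matched: dict[str, bool] = {}  # gt identity -> matched on its last frame
    in_gap: dict[str, bool] = {}
    persistent: dict[str, str] = {}
    correspondences: dict[int, dict[str, str]] = {}

    for frame in sorted(set(gt_frames) | set(pred_frames)):
        gt = gt_frames.get(frame, {})
        pred = pred_frames.get(frame, {})
        matches = frame_match(gt, pred, iou_threshold, persistent)
        correspondences[frame] = matches
        misses += len(gt) - len(matches)
        fp += len(pred) - len(matches)
        for g in gt:
            matched = g in matches
            if matched:
                p = matches[g]
                if g in last_pred and last_pred[g] != p:
                    switches += 1
                if in_gap.get(g):
                    frag += 1
                last_pred[g] = p
                in_gap[g] = False
            elif prev_matched.get(g, False) or in_gap.get(g, False):
                in_gap[g] = True
            prev_matched[g] = matched
        persistent = matches
    mota = 1.0 - (misses + fp + switches) / num_gt
    return {
        "mota": mota,
        "misses": misses,
        "false_positives": fp,
        "id_switches": switches,
        "fragmentations": frag,
        "num_gt_boxes": num_gt,
        "correspondences": correspondences,
    }


def compute_id_metrics(
    gt_frames: dict[int, FrameBoxes],
    pred_frames: dict[int, FrameBoxes],
    iou_threshold: float = 0.5,
) -> dict:
    """IDP / IDR / IDF1 under a global trajectory-to-trajectory matching.

    For each (gt trajectory, predicted trajectory) pair the binary
    per-frame overlap (same camera, IoU >= threshold) is counted; a
    min-cost bipartite matching — equivalently, maximizing total overlap —
    fixes IDTP, and IDFN / IDFP follow from the total gt and predicted
    box counts.
    """
    total_gt = sum(len(b) for b in gt_frames.values())
    total_pred = sum(len(b) for b in pred_frames.values())
    if total_gt == 0:
        raise ValidationError("empty ground truth")
    gt_ids = sorted({g for b in gt_frames.values() for g in b})
    pr_ids = sorted({p for b in pred_frames.values() for p in b})
    overlap = np.zeros((len(gt_ids), len(pr_ids)))
    g_index = {g: i for i, g in enumerate(gt_ids)}
    p_index = {p: i for i, p in enumerate(pr_ids)}
    for frame, gt in gt_frames.items():
        pred = pred_frames.get(frame, {})
        for g, gbox in gt.items():
            for p, pbox in pred.items():
                if _iou_same_camera(gbox, pbox) >= iou_threshold:
                    overlap[g_index[g], p_index[p]] += 1
    idtp = 0.0
    if len(gt_ids) and len(pr_ids):
        rows, cols = linear_sum_assignment(-overlap)
        idtp = float(overlap[rows, cols].sum())
    idfn = total_gt - idtp
    idfp = total_pred - idtp
    idp = idtp / (idtp + idfp) if total_pred else 0.0
    idr = idtp / (idtp + idfn)
    idf1 = 2.0 * idtp / (2.0 * idtp + idfp + idfn)
    return {"idf1": idf1, "idp": idp, "idr": idr, "idtp": idtp, "idfp": idfp, "idfn": idfn}


def coverage_bands(
    gt_frames: dict[int, FrameBoxes],
    correspondences: dict[int, dict[str, str]],
) -> dict:
    """Mostly/Partially tracked and Mostly Lost counts per gt identity.

    Coverage = matched frames / lifespan.  MT requires coverage > 0.8,
    ML < 0.2; exact 0.2 / 0.8 fall in PT.
    """
    lifespan: dict[str, int] = {}
    matched: dict[str, int] = {}
    for frame, gt in gt_frames.items():
        for g in gt:
            lifespan[g] = lifespan.get(g, 0) + 1
            if g in correspondences.get(frame, {}):
                matched[g] = matched.get(g, 0) + 1
    mt = pt = ml = 0
    coverage = {}
    for g, life in lifespan.items():
        cov = matched.get(g, 0) / life
        coverage[g] = cov
        if cov > 0.8:
            mt += 1
        elif cov < 0.2:
            ml += 1
        else:
            pt += 1
    return {
        "mostly_tracked": mt,
        "partially_tracked": pt,
        "mostly_lost": ml,
        "coverage": coverage,
    }


def reid_confusion(
    gt_frames: dict[int, FrameBoxes],
    pred_frames: dict[int, FrameBoxes],
    iou_threshold: float = 0.5,
) -> dict[str, dict[str, float]]:
    """Row-percent confusion of ground-truth vs assigned identities.

    Every predicted box is attributed to the ground-truth box it overlaps
    best (IoU >= threshold, same camera), without one-to-one exclusivity:
    if two predicted identities sit on the same animal in one frame, both
    count, so a row may sum to more than 100%.
    """
    gt_ids = sorted({g for b in gt_frames.values() for g in b})
    pr_ids = sorted({p for b in pred_frames.values() for p in b})
    counts = {g: {p: 0 for p in pr_ids} for g in gt_ids}
    presence = {g: 0 for g in gt_ids}
    for frame, gt in gt_frames.items():
        for g in gt:
            presence[g] += 1
        for p, pbox in pred_frames.get(frame, {}).items():
            best_g, best_iou = None, 0.0
            for g, gbox in gt.items():
                ov = _iou_same_camera(gbox, pbox)
                if ov > best_iou:
                    best_g, best_iou = g, ov
            if best_g is not None and best_iou >= iou_threshold:
                counts[best_g][p] += 1
    return {
        g: {p: 100.0 * counts[g][p] / presence[g] for p in pr_ids}
        for g in gt_ids
        if presence[g]
    }


def evaluate_tracks(
    gt_tracks: list[Track],
    pred_tracks: list[Track],
    iou_threshold: float = 0.5,
    include_filled: bool = False,
) -> MOTReport:
    """Full evaluation of predicted tracks against ground truth.

    ``include_filled`` decides whether gap-filled (predicted-only) boxes
    count as predictions; by default only observed boxes are evaluated.
    """
    gt_frames = _tracks_by_frame(gt_tracks, include_filled=True)
    pred_frames = _tracks_by_frame(pred_tracks, include_filled=include_filled)
    clear = compute_clear_mot(gt_frames, pred_frames, iou_threshold)
    ident = compute_id_metrics(gt_frames, pred_frames, iou_threshold)
    bands = coverage_bands(gt_frames, clear["correspondences"])
    confusion = reid_confusion(gt_frames, pred_frames, iou_threshold)
    return MOTReport(
        mota=clear["mota"],
        idf1=ident["idf1"],
        idp=ident["idp"],
        idr=ident["idr"],
        misses=clear["misses"],
        false_positives=clear["false_positives"],
        id_switches=clear["id_switches"],
        fragmentations=clear["fragmentations"],
        mostly_tracked=bands["mostly_tracked"],
        partially_tracked=bands["partially_tracked"],
        mostly_lost=bands["mostly_lost"],
        num_gt_boxes=clear["num_gt_boxes"],
        reid_confusion=confusion,
    )
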