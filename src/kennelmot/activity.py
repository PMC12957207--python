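"""Actigraphy: displacement series, time binning, mobility, cutoff selection.

Activity is measured purely from tracking output: the Euclidean distance
in pixels between an animal's box center on the current frame and its
center on the previous available entry ("previous detection").  Summing
these per time bin (default one minute) gives an actigram; thresholding
them per frame splits time into ``mobile`` (moving from one point in
space to another) and ``immobile``.  The mobile/immobile cutoff is tuned
by sweeping candidate cutoffs over an ROC grid and maximizing Youden's
index J = sensitivity + specificity - 1 = TPR - FPR; the operating point
shipped as the default is 10.0 px per analyzed frame.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .core import Track, ValidationError

__all__ = [
    "ActivitySeries",
    "BinnedActivity",
    "ROCResult",
    "track_displacements",
    "bin_activity",
    "classify_mobility",
    "mobility_labels",
    "select_cutoff_youden",
    "rank_correlation",
    "normalize_minmax",
]

MOBILE = "mobile"
IMMOBILE = "immobile"


@dataclass
class ActivitySeries:
    """Unbinned per-frame displacements for one animal.

    ``frames[i]`` is the frame each displacement is attributed to (the
    *current* frame of the pair); ``values[i]`` is NaN for pairs spanning
    a camera change, which have no meaning in pixel units and are excluded
    from binning.
    """

    identity: str
    frames: np.ndarray  # int, strictly increasing
    values: np.ndarray  # float px, >= 0 or NaN

    def total(self) -> float:
        return float(np.nansum(self.values))


@dataclass
class BinnedActivity:
    """Actigram: summed displacement per half-open time bin."""

    identity: str
    bin_duration: float  # seconds
    values: np.ndarray   # px per bin


def track_displacements(track: Track) -> ActivitySeries:
    """Per-frame center displacements of a track.

    Pairs spanning a frame gap use the previous available entry; pairs
    spanning a camera switch yield NaN (unrelated pixel planes).  Tracks
    with fewer than two entries give an empty series.
    """
    frames, values = [], []
    for prev, cur in zip(track.entries, track.entries[1:]):
        frames.append(cur.frame)
        if prev.camera_id != cur.camera_id:
            values.append(np.nan)
        else:
            (px, py), (cx, cy) = prev.box.center, cur.box.center
            values.append(float(np.hypot(cx - px, cy - py)))
    return ActivitySeries(track.identity, np.asarray(frames, int), np.asarray(values))


def bin_activity(
    series: ActivitySeries,
    bin_duration: float = 60.0,
    fps: float = 25.0,
    subsample: int = 4,
) -> BinnedActivity:
    """Sum displacements over half-open time bins of ``bin_duration`` seconds.

    Bin k covers frames t with k <= t / frames_per_bin < k + 1 at the
    analyzed frame rate fps / subsample.  Total displacement is conserved:
    the bins sum to the (NaN-excluded) series sum.
    """
    if bin_duration <= 0:
        raise ValidationError(f"bin_duration must be positive, got {bin_duration}")
    frames_per_bin = bin_duration * fps / subsample
    if len(series.frames) == 0:
        return BinnedActivity(series.identity, bin_duration, np.zeros(0))
    idx = np.floor(series.frames / frames_per_bin).astype(int)
    n_bins = int(idx.max()) + 1
    values = np.zeros(n_bins)
    valid = ~np.isnan(series.values)
    np.add.at(values, idx[valid], series.values[valid])
    return BinnedActivity(series.identity, bin_duration, values)


def classify_mobility(displacement: float, cutoff: float = 10.0) -> str:
    """``mobile`` iff displacement strictly exceeds the cutoff."""
    if displacement < 0 or not np.isfinite(displacement):
        raise ValidationError(f"displacement must be >= 0, got {displacement}")
    return MOBILE if displacement > cutoff else IMMOBILE


def mobility_labels(displacements: np.ndarray, cutoff: float = 10.0) -> np.ndarray:
    """Vectorized frame-level mobile/immobile labels."""
    d = np.asarray(displacements, float)
    if np.any(d[np.isfinite(d)] < 0):
        raise ValidationError("displacements must be >= 0")
    return np.where(d > cutoff, MOBILE, IMMOBILE)


@dataclass
class ROCResult:
    """ROC sweep over candidate mobility cutoffs with Youden's index."""

    cutoffs: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray
    youden: np.ndarray  # elementwise TPR - FPR
    best_cutoff: float
    best_youden: float


def select_cutoff_youden(
    displacements: np.ndarray,
    labels: np.ndarray,
    lo: float = 0.0,
    hi: float = 20.0,
    step: float = 0.01,
) -> ROCResult:
    """Exhaustive ROC sweep maximizing Youden's index J = TPR - FPR.

    Candidate cutoffs form the closed grid [lo, hi] in ``step`` increments
    (default 0 to 20 by 0.01).  ``mobile`` is the positive class and a
    frame is called mobile when its displacement strictly exceeds the
    cutoff, matching :func:`classify_mobility`.  Ties in J resolve to the
    smallest (most sensitive) cutoff.
    """
    d = np.asarray(displacements, float)
    lab = np.asarray(labels)
    if d.shape != lab.shape:
        raise ValidationError("displacements and labels must have equal length")
    if lab.dtype.kind == "b":
        positive = lab
    else:
        positive = lab == MOBILE
    n_pos, n_neg = int(positive.sum()), int((~positive).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValidationError("both mobile and immobile labels are required")

    n_steps = int(round((hi - lo) / step))
    cutoffs = lo + step * np.arange(n_steps + 1)
    pos_sorted = np.sort(d[positive])
    neg_sorted = np.sort(d[~positive])
    tpr = (n_pos - np.searchsorted(pos_sorted, cutoffs, side="right")) / n_pos
    fpr = (n_neg - np.searchsorted(neg_sorted, cutoffs, side="right")) / n_neg
    youden = tpr - fpr
    best = int(np.argmax(youden))  # first max = smallest cutoff
    return ROCResult(cutoffs, tpr, fpr, youden, float(cutoffs[best]), float(youden[best]))


def rank_correlation(series_a: np.ndarray, series_b: np.ndarray) -> float:
    """Spearman rank correlation (average ranks for ties)."""
    a = np.asarray(series_a, float)
    b = np.asarray(series_b, float)
    if a.shape != b.shape:
        raise ValidationError("series must have equal length")
    if a.size < 3:
        raise ValidationError("need at least 3 points for a rank correlation")
    return float(stats.spearmanr(a, b).statistic)


def normalize_minmax(values: np.ndarray) -> np.ndarray:
    """Min-max normalization to [0, 1] for cross-instrument actigram overlay."""
    v = np.asarray(values, float)
    lo, hi = np.nanmin(v), np.nanmax(v)
    if hi == lo:
        return np.zeros_like(v)
    return (v - lo) / (hi - lo)
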