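"""Framewise class-label analytics: merging, binning, baseline thresholding.

Downstream behavior / clinical-sign classifiers emit one label per
analyzed frame per animal (eating, drinking, ataxia, ..., or the
background ``none``).  This module turns those frame streams into
reviewable quantities:

* per-minute prediction counts per class (``bin_minutes``),
* a centered moving average over minutes (default 5-min window) to give
  isolated predictions temporal context,
* adaptive per-animal, per-class baseline thresholds — the smallest
  suppression level that removes *every* prediction of a class during
  the pre-treatment baseline period — applied to the treatment day so
  only above-baseline signal survives,
* bout-level event extraction and the event-level accuracy
  ``100 * correct / (predicted + missed)``.

Class merging (eating-hopper + eating-bowl -> eating; ataxia + limping ->
abnormal gait) happens before binning and commutes with it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import ValidationError

__all__ = [
    "BACKGROUND",
    "ClassSeries",
    "MinuteBins",
    "BaselineThresholds",
    "Event",
    "merge_classes",
    "bin_minutes",
    "moving_average",
    "fit_baseline_thresholds",
    "apply_thresholds",
    "extract_events",
    "event_accuracy",
    "match_events",
]

BACKGROUND = "none"

#: Default label inventory of the behavior + clinical-observation classifiers.
DEFAULT_LABEL_SET: tuple[str, ...] = (
    "eating-hopper",
    "eating-bowl",
    "drinking",
    "ataxia",
    "limping",
    "IVM",
    "circling",
    "convulsion",
    "head shaking",
    "anxiety",
    "limb stiff",
    "vomiting",
    BACKGROUND,
)

#: Post-processing merges: eating subclasses recombine; the two abnormal-gait
#: phenotypes pool for analysis against baseline noise.
EATING_MERGE = {"eating-hopper": "eating", "eating-bowl": "eating"}
GAIT_MERGE = {"ataxia": "abnormal-gait", "limping": "abnormal-gait"}


@dataclass
class ClassSeries:
    """One predicted class label per analyzed frame for one animal."""

    identity: str
    labels: np.ndarray  # dtype object/str, one entry per frame starting at 0
    label_set: tuple[str, ...] = DEFAULT_LABEL_SET

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=object)
        unknown = set(self.labels) - set(self.label_set)
        if unknown:
            raise ValidationError(f"labels outside the configured set: {sorted(unknown)}")

    def __len__(self) -> int:
        return len(self.labels)


@dataclass
class MinuteBins:
    """Per-minute prediction counts (or smoothed rates) per class."""

    identity: str
    counts: pd.DataFrame  # index = minute, columns = classes

    def classes(self) -> tuple[str, ...]:
        return tuple(self.counts.columns)


@dataclass
class BaselineThresholds:
    """Per (animal, class) suppression levels in predictions/minute."""

    thresholds: dict[tuple[str, str], float] = field(default_factory=dict)

    def get(self, identity: str, cls: str) -> float:
        key = (identity, cls)
        if key not in self.thresholds:
            raise ValidationError(f"no baseline threshold for {key}")
        return self.thresholds[key]


@dataclass(frozen=True)
class Event:
    """A bout of one class over the half-open frame interval [start, end)."""

    cls: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValidationError(f"event end {self.end} must exceed start {self.start}")

    @property
    def duration(self) -> int:
        return self.end - self.start

    def overlap(self, other: "Event") -> int:
        return max(0, min(self.end, other.end) - max(self.start, other.start))


def merge_classes(series: ClassSeries, mapping: dict[str, str]) -> ClassSeries:
    """Replace labels by their image under ``mapping``; others pass through."""
    unknown = set(mapping) - set(series.label_set)
    if unknown:
        raise ValidationError(f"mapping from labels outside the set: {sorted(unknown)}")
    merged_set = []
    for lbl in series.label_set:
        tgt = mapping.get(lbl, lbl)
        if tgt not in merged_set:
            merged_set.append(tgt)
    labels = np.array([mapping.get(l, l) for l in series.labels], dtype=object)
    return ClassSeries(series.identity, labels, tuple(merged_set))


def frames_per_minute(fps: float = 25.0, subsample: int = 4) -> float:
    return 60.0 * fps / subsample


def bin_minutes(
    series: ClassSeries, fps: float = 25.0, subsample: int = 4
) -> MinuteBins:
    """Count predictions per class within each half-open minute window."""
    fpm = frames_per_minute(fps, subsample)
    n = len(series)
    n_minutes = int(np.floor((n - 1) / fpm)) + 1 if n else 0
    minutes = np.floor(np.arange(n) / fpm).astype(int)
    df = pd.DataFrame(
        0, index=pd.RangeIndex(n_minutes, name="minute"), columns=list(series.label_set)
    )
    if n:
        counts = pd.crosstab(minutes, series.labels)
        df.loc[counts.index, counts.columns] = counts.values
    return MinuteBins(series.identity, df.astype(float))


def moving_average(bins: MinuteBins, window: int = 5) -> MinuteBins:
    """Centered moving average over minutes with truncated edges.

    Edge minutes average over however many neighbors exist inside the
    series, so constant series map to themselves and totals shift only
    at the boundaries.
    """
    if window <= 0 or window % 2 == 0:
        raise ValidationError(f"window must be an odd positive integer, got {window}")
    if window == 1 or bins.counts.empty:
        return MinuteBins(bins.identity, bins.counts.copy())
    kernel = np.ones(window)
    denom = np.convolve(np.ones(len(bins.counts)), kernel, mode="same")
    smoothed = {
        col: np.convolve(bins.counts[col].to_numpy(), kernel, mode="same") / denom
        for col in bins.counts.columns
    }
    return MinuteBins(bins.identity, pd.DataFrame(smoothed, index=bins.counts.index))


def fit_baseline_thresholds(
    baseline: dict[str, MinuteBins] | list[MinuteBins],
) -> BaselineThresholds:
    """Per (animal, class) threshold = maximum smoothed baseline bin value.

    This is the smallest level T such that zeroing all bins <= T removes
    every baseline prediction of that class for that animal, so applying
    the thresholds back to the baseline itself yields all-zero bins.
    Multiple baseline-day bins for one animal are pooled (max over all).
    """
    items = list(baseline.values()) if isinstance(baseline, dict) else list(baseline)
    if not items:
        raise ValidationError("baseline period is empty")
    thresholds: dict[tuple[str, str], float] = {}
    for mb in items:
        if mb.counts.empty:
            raise ValidationError(f"baseline for {mb.identity!r} has no minutes")
        for cls in mb.counts.columns:
            key = (mb.identity, cls)
            peak = float(mb.counts[cls].max())
            thresholds[key] = max(thresholds.get(key, 0.0), peak)
    return BaselineThresholds(thresholds)


def apply_thresholds(
    dosing: MinuteBins, thresholds: BaselineThresholds
) -> MinuteBins:
    """Suppress dosing-day bins at or below the baseline threshold.

    Bins <= threshold become 0 (the baseline maximum itself must be
    suppressed); strictly greater bins pass through unchanged.
    """
    out = dosing.counts.copy()
    for cls in out.columns:
        t = thresholds.get(dosing.identity, cls)
        col = out[cls].to_numpy(float)
        out[cls] = np.where(col > t, col, 0.0)
    return MinuteBins(dosing.identity, out)


def extract_events(
    series: ClassSeries,
    min_duration_frames: int = 25,
    max_gap_frames: int = 12,
    background: str = BACKGROUND,
) -> list[Event]:
    """Segment a label series into per-class bouts.

    Per class: maximal runs, then runs separated by gaps of at most
    ``max_gap_frames`` frames are merged (the merged duration includes the
    gap), then bouts shorter than ``min_duration_frames`` are dropped.
    The background class yields no events.  Defaults (gap 12, minimum 25
    analyzed frames = 4 s at 25/4 fps) suit bout-like behaviors.
    """
    events: list[Event] = []
    labels = series.labels
    n = len(labels)
    for cls in series.label_set:
        if cls == background:
            continue
        runs: list[list[int]] = []
        i = 0
        while i < n:
            if labels[i] == cls:
                j = i
                while j < n and labels[j] == cls:
                    j += 1
                if runs and i - runs[-1][1] <= max_gap_frames:
                    runs[-1][1] = j
                else:
                    runs.append([i, j])
                i = j
            else:
                i += 1
        events.extend(
            Event(cls, s, e) for s, e in runs if e - s >= min_duration_frames
        )
    return sorted(events, key=lambda e: (e.start, e.cls))


def event_accuracy(correct: int, predicted_total: int, missed: int) -> float:
    """Event-level accuracy in percent: 100 * correct / (predicted + missed)."""
    if min(correct, predicted_total, missed) < 0:
        raise ValidationError("counts must be non-negative")
    if correct > predicted_total:
        raise ValidationError("correct events cannot exceed predicted events")
    denom = predicted_total + missed
    if denom == 0:
        raise ValidationError("predicted + missed must be positive")
    return 100.0 * correct / denom


def match_events(
    predicted: list[Event],
    truth: list[Event],
    min_overlap_fraction: float = 0.5,
) -> tuple[int, int, int]:
    """Greedy one-to-one temporal matching of predicted to truth events.

    A predicted event counts as correct when its overlap covers at least
    ``min_overlap_fraction`` of the truth event's duration; each predicted
    event can validate at most one truth event.  Returns
    (correct, false_positives, missed).
    """
    used: set[int] = set()
    correct = 0
    for t in truth:
        best_i, best_ov = None, 0
        for i, p in enumerate(predicted):
            if i in used or p.cls != t.cls:
                continue
            ov = p.overlap(t)
            if ov > best_ov and ov / t.duration >= min_overlap_fraction:
                best_i, best_ov = i, ov
        if best_i is not None:
            used.add(best_i)
            correct += 1
    false_positives = len(predicted) - len(used)
    missed = len(truth) - correct
    return correct, false_positives, missed
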