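"""Temporal layer: per-identity Kalman filtering, gap filling, lifecycle.

Each identity carries an 8-dimensional constant-velocity Kalman state on
(center_x, center_y, width, height) and their per-analyzed-frame
velocities; the measurement is the assigned box as (cx, cy, w, h).  The
filter smooths abrupt box changes and predicts through missed detections:
frames where an identity goes unassigned are emitted as ``filled``
entries from the prediction alone, for at most ``max_gap_frames``
consecutive frames, after which the state is retired and the identity
waits for reacquisition.

Identity labels are decided upstream by the frame assignment; this module
never swaps them.  When an identity reappears on a *different* camera its
state is re-initialized from the new observation — there is no
cross-camera motion model, and gap filling never crosses cameras.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

from .core import (
    BoundingBox,
    Detection,
    FrameAssignment,
    Track,
    TrackEntry,
    TrackerConfig,
    ValidationError,
    group_by_frame,
    validate_identity_set,
)
from .assignment import build_score_matrix, assign_ids

__all__ = [
    "KalmanState",
    "init_state",
    "kalman_predict",
    "kalman_update",
    "step_tracks",
    "MultiAnimalTracker",
    "track_detections",
]

_DIM = 8
_MIN_EXTENT = 1e-3
# initial velocity variance: scaled with measurement variance but floored at
# a plausible animal-speed spread so a clean stream still re-estimates velocity
_INIT_VEL_VAR = 1e4
_BASE_VEL_VAR = 100.0  # (10 px/frame)^2

# constant-velocity transition and measurement matrices (dt = 1 analyzed frame)
_F = np.eye(_DIM)
_F[:4, 4:] = np.eye(4)
_H = np.zeros((4, _DIM))
_H[:4, :4] = np.eye(4)


def _process_noise(q: float) -> np.ndarray:
    """Discrete white-noise-acceleration covariance per (position, velocity) pair."""
    Q = np.zeros((_DIM, _DIM))
    q2 = q * q
    for i in range(4):
        Q[i, i] = q2 / 4.0
        Q[i, i + 4] = Q[i + 4, i] = q2 / 2.0
        Q[i + 4, i + 4] = q2
    return Q


@dataclass(frozen=True)
class KalmanState:
    """Filter state for one identity on one camera."""

    x: np.ndarray            # (8,) state mean
    P: np.ndarray            # (8, 8) covariance
    camera_id: str
    frame: int               # frame of the last emitted entry
    last_observed_frame: int
    missed: int = 0          # consecutive frames without an observation

    def box(self) -> BoundingBox:
        cx, cy, w, h = self.x[:4]
        w = max(float(w), _MIN_EXTENT)
        h = max(float(h), _MIN_EXTENT)
        return BoundingBox(float(cx) - w / 2.0, float(cy) - h / 2.0, w, h)


def _measurement(box: BoundingBox) -> np.ndarray:
    cx, cy = box.center
    return np.array([cx, cy, box.width, box.height])


def init_state(
    box: BoundingBox, frame: int, camera_id: str, config: TrackerConfig
) -> KalmanState:
    """Start a track from a first observation: zero velocity, inflated covariance."""
    x = np.zeros(_DIM)
    x[:4] = _measurement(box)
    r2 = max(config.measurement_noise**2, 1e-12)
    vel_var = r2 * _INIT_VEL_VAR + _BASE_VEL_VAR
    P = np.diag([r2] * 4 + [vel_var] * 4)
    return KalmanState(x, P, camera_id, frame, frame, missed=0)


def kalman_predict(state: KalmanState, config: TrackerConfig) -> KalmanState:
    """Propagate one analyzed frame under the constant-velocity model."""
    x = _F @ state.x
    P = _F @ state.P @ _F.T + _process_noise(config.process_noise)
    return replace(state, x=x, P=P)


def kalman_update(
    state: KalmanState, observation: BoundingBox, config: TrackerConfig
) -> KalmanState:
    """Standard linear Kalman correction with the box as the measurement."""
    z = _measurement(observation)
    if not np.all(np.isfinite(z)):
        raise ValidationError("non-finite observation")
    R = np.eye(4) * max(config.measurement_noise**2, 1e-12)
    S = _H @ state.P @ _H.T + R
    K = state.P @ _H.T @ np.linalg.solve(S, np.eye(4))
    x = state.x + K @ (z - _H @ state.x)
    # Joseph form keeps the covariance symmetric positive semi-definite
    A = np.eye(_DIM) - K @ _H
    P = A @ state.P @ A.T + K @ R @ K.T
    return replace(state, x=x, P=(P + P.T) / 2.0)


def step_tracks(
    states: dict[str, KalmanState],
    assignment: FrameAssignment,
    frame: int,
    config: TrackerConfig,
) -> tuple[dict[str, KalmanState], dict[str, TrackEntry]]:
    """Advance every identity by one analyzed frame.

    Assigned identities are predicted and corrected (entry source
    ``observed``, smoothed box).  Unassigned identities with a live state
    are predicted only (source ``filled``) while the consecutive gap stays
    within ``max_gap_frames``; beyond that the state is retired and nothing
    is emitted until the identity is assigned again.
    """
    new_states: dict[str, KalmanState] = {}
    entries: dict[str, TrackEntry] = {}

    for ident, state in states.items():
        if frame <= state.frame:
            raise ValidationError(
                f"frame {frame} not after last processed frame {state.frame} "
                f"for identity {ident!r}"
            )

    for ident, pair in assignment.pairs.items():
        det = pair.detection
        state = states.get(ident)
        if state is None or state.camera_id != det.camera_id:
            # fresh track, or camera handoff: restart from the observation
            state = init_state(det.box, frame, det.camera_id, config)
        else:
            state = kalman_predict(state, config)
            state = kalman_update(state, det.box, config)
        state = replace(state, frame=frame, last_observed_frame=frame, missed=0)
        new_states[ident] = state
        entries[ident] = TrackEntry(frame, det.camera_id, state.box(), "observed")

    for ident, state in states.items():
        if ident in assignment.pairs:
            continue
        missed = state.missed + 1
        if missed > config.max_gap_frames:
            continue  # retired; no entry
        state = kalman_predict(state, config)
        state = replace(state, frame=frame, missed=missed)
        new_states[ident] = state
        entries[ident] = TrackEntry(frame, state.camera_id, state.box(), "filled")

    return new_states, entries


class MultiAnimalTracker:
    """Streaming tracker: score -> assign -> Kalman, one analyzed frame at a time.

    Drop-in pipeline over :func:`build_score_matrix`, :func:`assign_ids`
    and :func:`step_tracks`.  Feed frames in increasing order (empty
    detection lists are fine and drive gap filling / retirement).
    """

    def __init__(
        self,
        identities: Sequence[str],
        config: TrackerConfig | None = None,
    ) -> None:
        self.identities = validate_identity_set(identities)
        self.config = config if config is not None else TrackerConfig()
        self.states: dict[str, KalmanState] = {}
        self._tracks: dict[str, Track] = {i: Track(i) for i in self.identities}
        self.last_assignment: FrameAssignment | None = None

    def _prev_boxes(self) -> dict[str, tuple[str, BoundingBox]]:
        # previous box per identity = last emitted (observed or filled) box,
        # available only while the state is live
        return {i: (s.camera_id, s.box()) for i, s in self.states.items()}

    def step(self, frame: int, detections: list[Detection]) -> FrameAssignment:
        matrix = build_score_matrix(
            detections, self._prev_boxes(), self.config, self.identities
        )
        if matrix.frame >= 0 and matrix.frame != frame:
            raise ValidationError(
                f"detections carry frame {matrix.frame}, expected {frame}"
            )
        matrix.frame = frame
        assignment = assign_ids(matrix)
        self.states, entries = step_tracks(
            self.states, assignment, frame, self.config
        )
        for ident, entry in entries.items():
            self._tracks[ident].append(entry)
        self.last_assignment = assignment
        return assignment

    @property
    def tracks(self) -> list[Track]:
        return [self._tracks[i] for i in self.identities if len(self._tracks[i])]


def track_detections(
    detections: Iterable[Detection],
    config: TrackerConfig | None = None,
    identities: Sequence[str] | None = None,
) -> list[Track]:
    """Run the full tracking pipeline over a detection stream.

    Frames between the first and last detection frame are processed
    contiguously, so identities missing from intermediate frames are
    gap-filled (up to ``max_gap_frames``) or retired.
    """
    grouped = group_by_frame(detections)
    if not grouped:
        return []
    if identities is None:
        identities = tuple(grouped[0][1][0].id_conf)
    tracker = MultiAnimalTracker(identities, config)
    by_frame = dict(grouped)
    for frame in range(grouped[0][0], grouped[-1][0] + 1):
        tracker.step(frame, by_frame.get(frame, []))
    return tracker.tracks
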