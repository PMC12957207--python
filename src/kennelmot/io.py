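"""Readers and writers for the toolkit's table formats.

All tables are comma-separated UTF-8 with a mandatory header and "."
decimals.  Detection tables carry one row per candidate box
(``camera_id, frame, x, y, w, h, det_conf, cr_<ID>...``); track tables
one row per emitted entry (``identity, frame, camera_id, x, y, w, h,
source``).  Reader/writer pairs round-trip losslessly.  Tracks can also
be exported in the MOTChallenge text layout for use with external
evaluation tooling.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

from .core import (
    BoundingBox,
    Detection,
    Track,
    TrackEntry,
    TrackerConfig,
    ValidationError,
    validate_identity_set,
)
from .events import ClassSeries, Event, MinuteBins

__all__ = [
    "read_detections",
    "write_detections",
    "read_tracks",
    "write_tracks",
    "write_motchallenge",
    "read_class_series",
    "write_class_series",
    "read_minute_bins",
    "write_minute_bins",
    "read_events",
    "write_events",
    "load_config",
]

_DET_COLUMNS = ["camera_id", "frame", "x", "y", "w", "h", "det_conf"]


def _require_columns(df: pd.DataFrame, needed: Sequence[str], path) -> None:
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing column(s) {', '.join(missing)}")


def read_detections(path, identities: Sequence[str]) -> list[Detection]:
    """Parse a detection CSV; rows keep file order.

    Confidence columns are ``det_conf`` plus one ``cr_<ID>`` column per
    identity in the configured set; values outside [0, 1] are rejected
    with the offending row number (1-based, excluding the header).
    """
    ids = validate_identity_set(identities)
    df = pd.read_csv(path, float_precision="round_trip")
    cr_cols = [f"cr_{i}" for i in ids]
    _require_columns(df, _DET_COLUMNS + cr_cols, path)
    records = df.to_dict("records")
    detections = []
    for row_no, rec in enumerate(records, start=1):
        try:
            box = BoundingBox(float(rec["x"]), float(rec["y"]),
                              float(rec["w"]), float(rec["h"]))
            det = Detection(
                camera_id=str(rec["camera_id"]),
                frame=int(rec["frame"]),
                box=box,
                det_conf=float(rec["det_conf"]),
                id_conf={i: float(rec[c]) for i, c in zip(ids, cr_cols)},
            )
        except (ValidationError, ValueError, KeyError) as exc:
            raise ValidationError(f"{path}: row {row_no}: {exc}") from exc
        detections.append(det)
    return detections


def write_detections(detections: Sequence[Detection], path) -> None:
    if detections:
        ids = tuple(detections[0].id_conf)
    else:
        ids = ()
    rows = [
        {
            "camera_id": d.camera_id,
            "frame": d.frame,
            "x": d.box.x,
            "y": d.box.y,
            "w": d.box.width,
            "h": d.box.height,
            "det_conf": d.det_conf,
            **{f"cr_{i}": d.id_conf[i] for i in ids},
        }
        for d in detections
    ]
    cols = _DET_COLUMNS + [f"cr_{i}" for i in ids]
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False)


_TRACK_COLUMNS = ["identity", "frame", "camera_id", "x", "y", "w", "h", "source"]


def write_tracks(tracks: Sequence[Track], path) -> None:
    rows = [
        {
            "identity": tr.identity,
            "frame": e.frame,
            "camera_id": e.camera_id,
            "x": e.box.x,
            "y": e.box.y,
            "w": e.box.width,
            "h": e.box.height,
            "source": e.source,
        }
        for tr in tracks
        for e in tr.entries
    ]
    pd.DataFrame(rows, columns=_TRACK_COLUMNS).to_csv(path, index=False)


def read_tracks(path) -> list[Track]:
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, _TRACK_COLUMNS, path)
    tracks: dict[str, Track] = {}
    for row in df.itertuples(index=False):
        tr = tracks.setdefault(str(row.identity), Track(str(row.identity)))
        tr.append(
            TrackEntry(
                int(row.frame),
                str(row.camera_id),
                BoundingBox(float(row.x), float(row.y), float(row.w), float(row.h)),
                str(row.source),
            )
        )
    return list(tracks.values())


def write_motchallenge(tracks: Sequence[Track], path, conf: float = 1.0) -> None:
    """MOTChallenge-format export: frame, numeric id, box, conf, -1, -1, -1.

    Frames are written 1-based as the format expects; identity labels map
    to numeric ids in first-seen order.
    """
    id_map = {tr.identity: k + 1 for k, tr in enumerate(tracks)}
    lines = []
    for tr in tracks:
        for e in tr.entries:
            lines.append(
                f"{e.frame + 1},{id_map[tr.identity]},{e.box.x:.2f},{e.box.y:.2f},"
                f"{e.box.width:.2f},{e.box.height:.2f},{conf},-1,-1,-1"
            )
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def write_class_series(series: Sequence[ClassSeries], path) -> None:
    rows = [
        {"identity": s.identity, "frame": f, "label": l}
        for s in series
        for f, l in enumerate(s.labels)
    ]
    pd.DataFrame(rows, columns=["identity", "frame", "label"]).to_csv(path, index=False)


def read_class_series(path, label_set: Sequence[str]) -> list[ClassSeries]:
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, ["identity", "frame", "label"], path)
    out = []
    for ident, grp in df.groupby("identity", sort=False):
        grp = grp.sort_values("frame")
        frames = grp["frame"].to_numpy()
        if len(frames) and (frames[0] != 0 or (frames[1:] - frames[:-1] != 1).any()):
            raise ValidationError(f"{path}: frames for {ident!r} are not contiguous from 0")
        out.append(ClassSeries(str(ident), grp["label"].to_numpy(object), tuple(label_set)))
    return out


def write_minute_bins(bins: Sequence[MinuteBins], path) -> None:
    rows = [
        {"identity": mb.identity, "minute": int(minute), "class": cls,
         "count": float(mb.counts.at[minute, cls])}
        for mb in bins
        for minute in mb.counts.index
        for cls in mb.counts.columns
    ]
    pd.DataFrame(rows, columns=["identity", "minute", "class", "count"]).to_csv(
        path, index=False
    )


def read_minute_bins(path) -> list[MinuteBins]:
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, ["identity", "minute", "class", "count"], path)
    out = []
    for ident, grp in df.groupby("identity", sort=False):
        wide = grp.pivot_table(index="minute", columns="class", values="count",
                               sort=False).fillna(0.0)
        wide.index.name = "minute"
        wide.columns.name = None
        # preserve the class order of the file
        wide = wide[list(dict.fromkeys(grp["class"]))]
        out.append(MinuteBins(str(ident), wide))
    return out


def write_events(events: Sequence[Event], path) -> None:
    rows = [{"class": e.cls, "start": e.start, "end": e.end} for e in events]
    pd.DataFrame(rows, columns=["class", "start", "end"]).to_csv(path, index=False)


def read_events(path) -> list[Event]:
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, ["class", "start", "end"], path)
    return [Event(str(r[0]), int(r[1]), int(r[2]))
            for r in df.itertuples(index=False)]


_CONFIG_KEYS = {f for f in TrackerConfig.__dataclass_fields__}


def load_config(path=None, overrides: dict | None = None) -> TrackerConfig:
    """Load a :class:`TrackerConfig` from YAML or JSON; absent keys default.

    The defaults are the published operating point (weights 1.0/0.75/1.0,
    retention threshold 0.5, mobility cutoff 10.0 px, subsample 4).
    """
    data: dict = {}
    if path is not None:
        text = Path(path).read_text()
        loaded = yaml.safe_load(text) if text.strip() else {}
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ValidationError(f"{path}: config must be a mapping")
        data.update(loaded)
    if overrides:
        data.update(overrides)
    unknown = set(data) - _CONFIG_KEYS
    if unknown:
        raise ValidationError(f"unknown config key(s): {sorted(unknown)}")
    return TrackerConfig(**data)
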