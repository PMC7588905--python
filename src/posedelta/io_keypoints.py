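"""Read, validate and write pose-frame streams and reference keypoint sets.

The on-disk stream format is NDJSON, one frame per line, mirroring the JSON
a single-person pose estimator emits per captured image::

    {"timestamp": 1598832000, "score": 0.93, "persons": 1,
     "keypoints": [{"part": "nose", "position": {"x": 161.2, "y": 104.7},
                    "score": 0.98}, ...]}

``timestamp`` is integer seconds on the 1 s capture grid; ``persons`` is the
number of detected people (frames store the single estimated pose even when
a visitor is present).  Timestamps must be strictly increasing; sub-second
timestamps are rejected rather than rounded.  The full schema is documented
in ``docs/ndjson-schema.md``.

Reference keypoint sets for the evaluation harness are accepted either as a
CSV of per-image box extents (``image_id,x_min,x_max,y_min,y_max``) or as a
JSON list of per-image keypoint lists, from which extents are derived.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from .features import BoundingBox, bbox_from_keypoints

__all__ = [
    "COCO_PARTS",
    "Keypoint",
    "PoseFrame",
    "ReferencePose",
    "StreamParseError",
    "StreamValidationError",
    "read_stream",
    "write_stream",
    "read_references",
    "scale_stream",
]

#: The 17-part keypoint vocabulary of single-person pose estimators.
COCO_PARTS: tuple[str, ...] = (
    "nose",
    "leftEye",
    "rightEye",
    "leftEar",
    "rightEar",
    "leftShoulder",
    "rightShoulder",
    "leftElbow",
    "rightElbow",
    "leftWrist",
    "rightWrist",
    "leftHip",
    "rightHip",
    "leftKnee",
    "rightKnee",
    "leftAnkle",
    "rightAnkle",
)

_PART_SET = frozenset(COCO_PARTS)


class StreamParseError(ValueError):
    """A line of the stream is not valid JSON."""


class StreamValidationError(ValueError):
    """A parsed record violates the stream invariants."""


@dataclass(frozen=True)
class Keypoint:
    """One named anatomical landmark in image coordinates."""

    part: str
    x: float
    y: float
    score: float

    def __post_init__(self) -> None:
        if self.part not in _PART_SET:
            raise StreamValidationError(f"unknown keypoint part {self.part!r}")
        if not 0.0 <= self.score <= 1.0:
            raise StreamValidationError(
                f"keypoint score must be in [0, 1], got {self.score}"
            )


@dataclass(frozen=True)
class PoseFrame:
    """One timestamped pose observation.

    ``persons`` counts detected people; when it is 0 the frame carries no
    keypoints (such frames exist only transiently in a pipeline — the
    monitored deployment never stores them).
    """

    timestamp: int
    score: float
    persons: int
    keypoints: tuple[Keypoint, ...]

    def __post_init__(self) -> None:
        if not isinstance(self.timestamp, int) or isinstance(self.timestamp, bool):
            raise StreamValidationError(
                f"timestamp must be integer seconds, got {self.timestamp!r}"
            )
        if not 0.0 <= self.score <= 1.0:
            raise StreamValidationError(f"score must be in [0, 1], got {self.score}")
        if self.persons < 0:
            raise StreamValidationError(f"persons must be >= 0, got {self.persons}")
        if self.persons == 0:
            if self.keypoints:
                raise StreamValidationError("persons=0 frame must have no keypoints")
        else:
            if len(self.keypoints) != len(COCO_PARTS):
                raise StreamValidationError(
                    f"expected {len(COCO_PARTS)} keypoints, got {len(self.keypoints)}"
                )
            parts = [kp.part for kp in self.keypoints]
            if len(set(parts)) != len(parts):
                dupes = sorted({p for p in parts if parts.count(p) > 1})
                raise StreamValidationError(f"duplicate keypoint parts: {dupes}")


@dataclass(frozen=True)
class ReferencePose:
    """Ground-truth box extent of one reference image."""

    image_id: str
    extent: BoundingBox


def _frame_from_obj(obj: dict, where: str) -> PoseFrame:
    try:
        ts = obj["timestamp"]
        score = obj["score"]
        persons = obj["persons"]
        raw_kps = obj["keypoints"]
    except (KeyError, TypeError) as exc:
        raise StreamValidationError(f"{where}: missing field {exc}") from exc
    if isinstance(ts, float):
        raise StreamValidationError(
            f"{where}: sub-second timestamp {ts!r} rejected (1 s grid required)"
        )
    try:
        kps = tuple(
            Keypoint(
                part=kp["part"],
                x=float(kp["position"]["x"]),
                y=float(kp["position"]["y"]),
                score=float(kp["score"]),
            )
            for kp in raw_kps
        )
        return PoseFrame(
            timestamp=ts, score=float(score), persons=int(persons), keypoints=kps
        )
    except StreamValidationError as exc:
        raise StreamValidationError(f"{where}: {exc}") from exc
    except (KeyError, TypeError, ValueError) as exc:
        raise StreamValidationError(f"{where}: malformed record ({exc})") from exc


def read_stream(path) -> list[PoseFrame]:
    """Read an NDJSON pose stream, validating every frame.

    Frames must be stored in strictly increasing timestamp order; streams
    violating the order (including duplicate timestamps) are rejected
    rather than silently sorted.
    """
    frames: list[PoseFrame] = []
    last_ts: int | None = None
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            where = f"{path}:{lineno}"
            try:
                obj = json.loads(line)
            except json.JSONDecodeError as exc:
                raise StreamParseError(f"{where}: invalid JSON ({exc.msg})") from exc
            frame = _frame_from_obj(obj, where)
            if last_ts is not None:
                if frame.timestamp == last_ts:
                    raise StreamValidationError(
                        f"{where}: duplicate timestamp {frame.timestamp}"
                    )
                if frame.timestamp < last_ts:
                    raise StreamValidationError(
                        f"{where}: timestamp {frame.timestamp} not increasing "
                        f"(previous {last_ts})"
                    )
            last_ts = frame.timestamp
            frames.append(frame)
    return frames


def _frame_to_obj(frame: PoseFrame) -> dict:
    return {
        "timestamp": frame.timestamp,
        "score": frame.score,
        "persons": frame.persons,
        "keypoints": [
            {"part": kp.part, "position": {"x": kp.x, "y": kp.y}, "score": kp.score}
            for kp in frame.keypoints
        ],
    }


def write_stream(frames: Iterable[PoseFrame], path) -> None:
    """Write frames as NDJSON; ``read_stream`` round-trips field-exactly.

    Floats are serialized with ``repr`` precision, so scores and
    coordinates survive the round trip bit-exactly.
    """
    with open(path, "w", encoding="utf-8") as fh:
        for frame in frames:
            fh.write(json.dumps(_frame_to_obj(frame), separators=(",", ":")))
            fh.write("\n")


def read_references(path) -> list[ReferencePose]:
    """Read reference extents from CSV, or keypoint lists from JSON.

    CSV files need the header ``image_id,x_min,x_max,y_min,y_max`` and are
    taken verbatim.  JSON files hold a list of objects with ``image_id``
    and either an ``extent`` object (same four fields) or a ``keypoints``
    list of ``{"x": ..., "y": ...}`` points, whose min/max extents are
    computed.  Records providing neither are rejected.
    """
    path = Path(path)
    if path.suffix.lower() == ".csv":
        return _read_references_csv(path)
    return _read_references_json(path)


def _read_references_csv(path: Path) -> list[ReferencePose]:
    import pandas as pd

    df = pd.read_csv(path)
    required = {"image_id", "x_min", "x_max", "y_min", "y_max"}
    missing = required - set(df.columns)
    if missing:
        raise StreamValidationError(
            f"{path}: missing reference columns {sorted(missing)}"
        )
    refs = []
    for row in df.itertuples(index=False):
        refs.append(
            ReferencePose(
                image_id=str(row.image_id),
                extent=BoundingBox(
                    x_min=float(row.x_min),
                    x_max=float(row.x_max),
                    y_min=float(row.y_min),
                    y_max=float(row.y_max),
                ),
            )
        )
    return refs


@dataclass(frozen=True)
class _Point:
    # minimal stand-in accepted by bbox_from_keypoints (reference keypoint
    # lists need no part names or scores)
    x: float
    y: float
    score: float = 1.0


def _read_references_json(path: Path) -> list[ReferencePose]:
    with open(path, "r", encoding="utf-8") as fh:
        data = json.load(fh)
    if not isinstance(data, list):
        raise StreamValidationError(f"{path}: expected a JSON list of records")
    refs = []
    for i, rec in enumerate(data):
        where = f"{path}[{i}]"
        image_id = rec.get("image_id")
        if image_id is None:
            raise StreamValidationError(f"{where}: missing image_id")
        if "keypoints" in rec and rec["keypoints"]:
            pts = [
                _Point(x=float(p["x"]), y=float(p["y"])) for p in rec["keypoints"]
            ]
            extent = bbox_from_keypoints(pts)
        elif "extent" in rec:
            ext = rec["extent"]
            extent = BoundingBox(
                x_min=float(ext["x_min"]),
                x_max=float(ext["x_max"]),
                y_min=float(ext["y_min"]),
                y_max=float(ext["y_max"]),
            )
        else:
            raise StreamValidationError(
                f"{where}: record needs 'keypoints' or 'extent'"
            )
        refs.append(ReferencePose(image_id=str(image_id), extent=extent))
    return refs


def scale_stream(frames: Sequence[PoseFrame], factor: float) -> list[PoseFrame]:
    """Multiply every keypoint coordinate by ``factor`` (unit change).

    Deltas, minute means and daily totals are pixel-covariant, so scaling
    a stream scales every downstream quantity by the same factor.
    """
    if factor <= 0:
        raise ValueError("factor must be positive")
    return [
        PoseFrame(
            timestamp=f.timestamp,
            score=f.score,
            persons=f.persons,
            keypoints=tuple(
                Keypoint(part=kp.part, x=kp.x * factor, y=kp.y * factor, score=kp.score)
                for kp in f.keypoints
            ),
        )
        for f in frames
    ]
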