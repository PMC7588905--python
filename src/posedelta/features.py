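"""Bounding-box delta features from pose keypoints.

A person's pose in one frame is reduced to the axis-aligned bounding box of
its keypoints.  Between two boxes (consecutive frames of a monitored scene,
or a predicted box versus a reference box) three nonnegative change metrics
are defined:

* ``d_height`` — absolute change of box height, in pixels.  A large value
  signals a posture transition (standing up / sitting down / lying down),
  the *pose conversion* parameter.
* ``d_width`` — absolute change of box width.  In-place limb and hand
  activity widens and narrows the box, the *body movement* parameter.
* ``d_distance`` — Euclidean displacement of the box center.  Locomotion
  within the room, the *positional changes* parameter.

The channel→parameter mapping above is the package default and is
configurable (see :data:`DEFAULT_CHANNEL_MAP`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import TYPE_CHECKING, Iterable, Mapping, Sequence

import pandas as pd

if TYPE_CHECKING:  # pragma: no cover - typing only
    from .io_keypoints import Keypoint, PoseFrame

__all__ = [
    "BoundingBox",
    "DeltaRecord",
    "MetricName",
    "FilterPolicy",
    "EmptyPoseError",
    "DEFAULT_CHANNEL_MAP",
    "TIE_PRIORITY",
    "bbox_from_keypoints",
    "delta_metrics",
    "frame_is_valid",
    "compute_deltas",
    "label_dominant",
    "write_deltas_csv",
    "read_deltas_csv",
]


class EmptyPoseError(ValueError):
    """No keypoint passed the per-keypoint score filter."""


class MetricName(str, Enum):
    """The three evaluated postural-change parameters."""

    POSE_CONVERSION = "pose_conversion"
    BODY_MOVEMENT = "body_movement"
    POSITIONAL_CHANGE = "positional_change"


#: Default mapping from delta channel to monitored parameter.
DEFAULT_CHANNEL_MAP: Mapping[str, MetricName] = {
    "d_height": MetricName.POSE_CONVERSION,
    "d_width": MetricName.BODY_MOVEMENT,
    "d_distance": MetricName.POSITIONAL_CHANGE,
}

#: Tie-break priority for :func:`label_dominant` (higher wins on equal deltas).
TIE_PRIORITY: Mapping[MetricName, int] = {
    MetricName.POSITIONAL_CHANGE: 3,
    MetricName.BODY_MOVEMENT: 2,
    MetricName.POSE_CONVERSION: 1,
}


@dataclass(frozen=True)
class BoundingBox:
    """Axis-aligned extent of a pose, image coordinates (y grows downward)."""

    x_min: float
    x_max: float
    y_min: float
    y_max: float

    def __post_init__(self) -> None:
        if self.x_min > self.x_max:
            raise ValueError(f"x_min {self.x_min} > x_max {self.x_max}")
        if self.y_min > self.y_max:
            raise ValueError(f"y_min {self.y_min} > y_max {self.y_max}")

    @property
    def width(self) -> float:
        return self.x_max - self.x_min

    @property
    def height(self) -> float:
        return self.y_max - self.y_min

    @property
    def center(self) -> tuple[float, float]:
        return ((self.x_min + self.x_max) / 2.0, (self.y_min + self.y_max) / 2.0)


@dataclass(frozen=True)
class DeltaRecord:
    """Per-second change metrics between a pair of valid frames.

    ``timestamp`` is the later frame of the pair; ``gap`` the seconds
    between the two frames (1 on an unbroken 1 s stream).
    """

    timestamp: int
    d_height: float
    d_width: float
    d_distance: float
    gap: int

    def __post_init__(self) -> None:
        if min(self.d_height, self.d_width, self.d_distance) < 0:
            raise ValueError("delta channels must be nonnegative")
        if self.gap < 1:
            raise ValueError(f"gap must be >= 1, got {self.gap}")

    def channel(self, name: str) -> float:
        return {"d_height": self.d_height, "d_width": self.d_width,
                "d_distance": self.d_distance}[name]


@dataclass(frozen=True)
class FilterPolicy:
    """Frame-level validity rules applied before delta extraction.

    Parameters
    ----------
    score_threshold : float
        Minimum overall pose confidence for a frame to be used (default
        0.5, the estimation threshold of the monitored deployment).
    multi_person_mode : str
        ``"keep"`` retains frames where a visitor is present (their effect
        becomes part of the care-variation signal); ``"exclude"`` drops
        frames with more than one detected person.
    max_gap : int
        Largest timestamp gap, in seconds, across which a delta is still
        computed.  Pairs further apart (absence, lights off) emit nothing.
    min_kp_score : float
        Per-keypoint confidence floor for the bounding box (default 0:
        all keypoints of a valid frame are included).
    """

    score_threshold: float = 0.5
    multi_person_mode: str = "keep"
    max_gap: int = 2
    min_kp_score: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.score_threshold <= 1.0:
            raise ValueError("score_threshold must be in [0, 1]")
        if self.multi_person_mode not in ("keep", "exclude"):
            raise ValueError("multi_person_mode must be 'keep' or 'exclude'")
        if self.max_gap < 1:
            raise ValueError("max_gap must be >= 1")
        if not 0.0 <= self.min_kp_score <= 1.0:
            raise ValueError("min_kp_score must be in [0, 1]")


def bbox_from_keypoints(
    keypoints: Sequence["Keypoint"], min_kp_score: float = 0.0
) -> BoundingBox:
    """Axis-aligned box over all keypoints with score >= ``min_kp_score``.

    Raises :class:`EmptyPoseError` if no keypoint passes the filter.
    """
    xs = []
    ys = []
    for kp in keypoints:
        if kp.score >= min_kp_score:
            xs.append(kp.x)
            ys.append(kp.y)
    if not xs:
        raise EmptyPoseError(
            f"no keypoint with score >= {min_kp_score} (of {len(keypoints)} given)"
        )
    return BoundingBox(x_min=min(xs), x_max=max(xs), y_min=min(ys), y_max=max(ys))


def delta_metrics(
    prev: BoundingBox, curr: BoundingBox
) -> tuple[float, float, float]:
    """``(d_height, d_width, d_distance)`` between two boxes.

    All three are absolute magnitudes; the function is symmetric in its
    arguments.  Distance is between box centers, the only
    translation-symmetric anchor.
    """
    d_height = abs(curr.height - prev.height)
    d_width = abs(curr.width - prev.width)
    (cx0, cy0), (cx1, cy1) = prev.center, curr.center
    d_distance = math.hypot(cx1 - cx0, cy1 - cy0)
    return d_height, d_width, d_distance


def frame_is_valid(frame: "PoseFrame", policy: FilterPolicy) -> bool:
    """Whether a frame passes the policy (score, person-count, non-empty)."""
    if frame.persons == 0:
        return False
    if frame.score < policy.score_threshold:
        return False
    if policy.multi_person_mode == "exclude" and frame.persons > 1:
        return False
    if policy.min_kp_score > 0.0 and not any(
        kp.score >= policy.min_kp_score for kp in frame.keypoints
    ):
        return False
    return True


def compute_deltas(
    frames: Sequence["PoseFrame"], policy: FilterPolicy = FilterPolicy()
) -> list[DeltaRecord]:
    """Delta records for each surviving consecutive frame pair.

    Frames failing the policy are dropped; the surviving frames are then
    paired consecutively, and a record is emitted for each pair whose
    timestamp gap is at most ``policy.max_gap`` seconds.
    """
    records: list[DeltaRecord] = []
    prev_frame: "PoseFrame | None" = None
    prev_box: BoundingBox | None = None
    for frame in frames:
        if not frame_is_valid(frame, policy):
            continue
        box = bbox_from_keypoints(frame.keypoints, policy.min_kp_score)
        if prev_frame is not None:
            gap = frame.timestamp - prev_frame.timestamp
            if gap <= policy.max_gap:
                d_h, d_w, d_d = delta_metrics(prev_box, box)
                records.append(
                    DeltaRecord(
                        timestamp=frame.timestamp,
                        d_height=d_h,
                        d_width=d_w,
                        d_distance=d_d,
                        gap=gap,
                    )
                )
        prev_frame, prev_box = frame, box
    return records


def label_dominant(
    record: DeltaRecord,
    mapping: Mapping[str, MetricName] = DEFAULT_CHANNEL_MAP,
    tie_priority: Mapping[MetricName, int] = TIE_PRIORITY,
) -> MetricName | None:
    """Parameter whose delta channel is largest, or ``None`` if all zero.

    Ties are broken by ``tie_priority`` (default: positional change >
    body movement > pose conversion).
    """
    values = [(record.channel(ch), tie_priority[metric], metric)
              for ch, metric in mapping.items()]
    best_value, _, best_metric = max(values, key=lambda t: (t[0], t[1]))
    if best_value == 0.0:
        return None
    return best_metric


def write_deltas_csv(records: Iterable[DeltaRecord], path) -> None:
    """CSV export: ``timestamp,d_height,d_width,d_distance,gap``."""
    df = pd.DataFrame(
        [(r.timestamp, r.d_height, r.d_width, r.d_distance, r.gap) for r in records],
        columns=["timestamp", "d_height", "d_width", "d_distance", "gap"],
    )
    df.to_csv(path, index=False)


def read_deltas_csv(path) -> list[DeltaRecord]:
    df = pd.read_csv(path)
    return [
        DeltaRecord(
            timestamp=int(row.timestamp),
            d_height=float(row.d_height),
            d_width=float(row.d_width),
            d_distance=float(row.d_distance),
            gap=int(row.gap),
        )
        for row in df.itertuples(index=False)
    ]
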