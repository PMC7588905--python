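"""Synthetic per-second pose-frame streams with known ground truth.

The simulator emulates the monitored deployment: a single room imaged at
320 x 240 pixels, one frame per second, containing one person performing
scripted activities.  A stylized 17-keypoint articulated figure is placed
on the scene per second:

* ``stand`` — tall, narrow figure (box height ~94 px, width ~30 px);
* ``sit`` — same figure compressed to ~60 % standing height;
* ``lie`` — rotated figure, box much wider than tall;
* ``walk`` — the standing figure translating at constant speed, reversing
  direction at the room margins;
* ``hand_activity`` — the standing figure with wrists and elbows swinging
  outward periodically (widens and narrows the box every second);
* ``absent`` — no frame is emitted at all (an estimator that sees nobody
  stores nothing);
* ``visitor`` — a second person is present: frames report ``persons=2``
  while still carrying the subject's single estimated pose.

Additive Gaussian coordinate noise and Beta-distributed confidence scores
emulate estimator jitter.  Activity transitions are linearly interpolated
over a short ramp so posture-change spikes are finite and testable.  Every
emitted or omitted second carries a ground-truth label, which the
``minute_ground_truth`` / ``dominant_match_rate`` helpers turn into a
recovery benchmark for the delta-classification pipeline.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .features import (
    DEFAULT_CHANNEL_MAP,
    DeltaRecord,
    MetricName,
    label_dominant,
)
from .io_keypoints import COCO_PARTS, Keypoint, PoseFrame

__all__ = [
    "ACTIVITIES",
    "ActivitySegment",
    "ScoreModel",
    "SimConfig",
    "SecondLabel",
    "SimResult",
    "ScheduleError",
    "skeleton_template",
    "simulate",
    "expected_channel",
    "minute_ground_truth",
    "dominant_match_rate",
    "demo_schedule",
    "load_config",
    "write_labels_csv",
]

ACTIVITIES = frozenset(
    {"stand", "sit", "walk", "lie", "hand_activity", "absent", "visitor"}
)

#: Default hand-wave amplitude (px) and oscillation period (s).
DEFAULT_WAVE_AMP = 12.0
DEFAULT_WAVE_PERIOD = 4
#: Default walking speed, px/s (~0.5 m/s at the 4 m ~ 320 px room scale).
DEFAULT_WALK_SPEED = 40.0

# room margins keeping the whole figure inside the frame
_MARGIN_X = 50.0
_MARGIN_Y_TOP = 100.0
_MARGIN_Y_BOT = 4.0


class ScheduleError(ValueError):
    """The activity schedule violates its invariants."""


@dataclass(frozen=True)
class ActivitySegment:
    """One scripted activity over ``[start, end)`` seconds.

    ``params`` is activity-specific: ``speed`` (px/s) and ``heading``
    (degrees) for walk; ``amp`` (px) and ``period`` (s) for
    hand_activity; ``subject_activity`` for visitor segments.
    """

    start: int
    end: int
    activity: str
    params: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.activity not in ACTIVITIES:
            raise ScheduleError(f"unknown activity {self.activity!r}")
        if not self.start < self.end:
            raise ScheduleError(
                f"segment must have start < end, got [{self.start}, {self.end})"
            )


@dataclass(frozen=True)
class ScoreModel:
    """Beta model for confidence scores: Beta(mean*conc, (1-mean)*conc)."""

    mean: float = 0.85
    concentration: float = 100.0

    def __post_init__(self) -> None:
        if not 0.0 < self.mean < 1.0:
            raise ValueError("score mean must be in (0, 1)")
        if self.concentration <= 0:
            raise ValueError("concentration must be positive")

    def sample(self, rng: np.random.Generator, size=None):
        a = self.mean * self.concentration
        b = (1.0 - self.mean) * self.concentration
        return rng.beta(a, b, size=size)


@dataclass(frozen=True)
class SimConfig:
    """Scene, noise and schedule of one simulation run."""

    schedule: tuple[ActivitySegment, ...]
    resolution: tuple[int, int] = (320, 240)
    noise_sd: float = 2.0
    score_model: ScoreModel = ScoreModel()
    seed: int = 0
    ramp_s: int = 3
    start_anchor: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        w, h = self.resolution
        if w <= 0 or h <= 0:
            raise ValueError("resolution must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.ramp_s < 1:
            raise ValueError("ramp_s must be >= 1")
        segs = sorted(self.schedule, key=lambda s: s.start)
        for a, b in zip(segs, segs[1:]):
            if a.end > b.start:
                raise ScheduleError(
                    f"segments overlap: [{a.start},{a.end}) and [{b.start},{b.end})"
                )
        object.__setattr__(self, "schedule", tuple(segs))
        if not self.schedule:
            raise ScheduleError("schedule must contain at least one segment")


@dataclass(frozen=True)
class SecondLabel:
    """Ground truth for one scheduled second.

    ``transition`` marks seconds whose emitted pose is a blend of two
    activity templates (posture-change ramp).
    """

    second: int
    activity: str
    persons: int
    transition: bool = False


@dataclass(frozen=True)
class SimResult:
    frames: list[PoseFrame]
    labels: list[SecondLabel]


# ---------------------------------------------------------------------------
# skeleton templates: (dx, dy) offsets from the figure anchor (ground-center
# point between the feet); y is negative upward in image coordinates.

_STAND: dict[str, tuple[float, float]] = {
    "nose": (0, -92), "leftEye": (-3, -95), "rightEye": (3, -95),
    "leftEar": (-6, -93), "rightEar": (6, -93),
    "leftShoulder": (-11, -80), "rightShoulder": (11, -80),
    "leftElbow": (-14, -62), "rightElbow": (14, -62),
    "leftWrist": (-15, -45), "rightWrist": (15, -45),
    "leftHip": (-8, -50), "rightHip": (8, -50),
    "leftKnee": (-8, -26), "rightKnee": (8, -26),
    "leftAnkle": (-8, -1), "rightAnkle": (8, -1),
}

_SIT: dict[str, tuple[float, float]] = {
    "nose": (0, -53), "leftEye": (-3, -56), "rightEye": (3, -56),
    "leftEar": (-6, -54), "rightEar": (6, -54),
    "leftShoulder": (-11, -44), "rightShoulder": (11, -44),
    "leftElbow": (-14, -30), "rightElbow": (14, -30),
    "leftWrist": (-13, -18), "rightWrist": (13, -18),
    "leftHip": (-9, -24), "rightHip": (9, -24),
    "leftKnee": (-12, -12), "rightKnee": (12, -12),
    "leftAnkle": (-12, -1), "rightAnkle": (12, -1),
}

_LIE: dict[str, tuple[float, float]] = {
    "nose": (-46, -12), "leftEye": (-48, -14), "rightEye": (-48, -10),
    "leftEar": (-46, -16), "rightEar": (-46, -8),
    "leftShoulder": (-34, -16), "rightShoulder": (-34, -8),
    "leftElbow": (-20, -18), "rightElbow": (-20, -6),
    "leftWrist": (-8, -18), "rightWrist": (-8, -6),
    "leftHip": (4, -14), "rightHip": (4, -10),
    "leftKnee": (24, -14), "rightKnee": (24, -10),
    "leftAnkle": (47, -14), "rightAnkle": (47, -10),
}


def skeleton_template(
    activity: str,
    phase: float = 0.0,
    params: Mapping[str, float] | None = None,
) -> dict[str, tuple[float, float]]:
    """17 named (dx, dy) offsets of the figure for one activity and phase.

    Deterministic in ``(activity, phase, params)``.  ``phase`` in [0, 1]
    drives periodic motion (the hand-activity wrist swing); static
    activities ignore it.  Walking uses the standing figure — locomotion
    is anchor translation, handled by :func:`simulate`.
    """
    params = params or {}
    if activity in ("stand", "walk"):
        return dict(_STAND)
    if activity == "sit":
        return dict(_SIT)
    if activity == "lie":
        return dict(_LIE)
    if activity == "hand_activity":
        amp = float(params.get("amp", DEFAULT_WAVE_AMP))
        s = (1.0 - math.cos(2.0 * math.pi * phase)) / 2.0
        tpl = dict(_STAND)
        tpl["leftWrist"] = (-(15.0 + amp * s), -45.0)
        tpl["rightWrist"] = (15.0 + amp * s, -45.0)
        tpl["leftElbow"] = (-(14.0 + 0.6 * amp * s), -62.0)
        tpl["rightElbow"] = (14.0 + 0.6 * amp * s, -62.0)
        return tpl
    if activity == "visitor":
        subject = str(params.get("subject_activity", "stand"))
        return skeleton_template(subject, phase, params)
    raise ValueError(f"activity {activity!r} has no skeleton template")


def _phase_of(seg: ActivitySegment, t: int) -> float:
    if seg.activity == "hand_activity" or (
        seg.activity == "visitor"
        and seg.params.get("subject_activity") == "hand_activity"
    ):
        period = int(seg.params.get("period", DEFAULT_WAVE_PERIOD))
        return ((t - seg.start) % period) / period
    return 0.0


def _templates_differ(
    a: Mapping[str, tuple[float, float]], b: Mapping[str, tuple[float, float]]
) -> bool:
    return any(a[p] != b[p] for p in COCO_PARTS)


def simulate(config: SimConfig) -> SimResult:
    """Run the schedule second by second; fully reproducible from the seed.

    Returns the emitted frames (one per non-absent scheduled second) and a
    ground-truth label for every second between the start of the first and
    the end of the last segment, absent seconds included.
    """
    rng = np.random.default_rng(config.seed)
    width, height = config.resolution
    anchor = (
        np.array(config.start_anchor, dtype=float)
        if config.start_anchor is not None
        else np.array([width / 2.0, height - 40.0], dtype=float)
    )
    x_lo, x_hi = _MARGIN_X, width - _MARGIN_X
    y_lo, y_hi = _MARGIN_Y_TOP, height - _MARGIN_Y_BOT

    frames: list[PoseFrame] = []
    labels: list[SecondLabel] = []

    segments = config.schedule
    seg_idx = 0
    walk_v = np.zeros(2)
    prev_poseful: ActivitySegment | None = None  # last non-absent segment seen

    t0, t_end = segments[0].start, segments[-1].end
    current: ActivitySegment | None = None
    for t in range(t0, t_end):
        # advance to the segment covering t (gaps between segments = absent)
        while seg_idx < len(segments) and t >= segments[seg_idx].end:
            if segments[seg_idx].activity != "absent":
                prev_poseful = segments[seg_idx]
            seg_idx += 1
        seg = segments[seg_idx] if seg_idx < len(segments) else None
        in_seg = seg is not None and seg.start <= t < seg.end
        if not in_seg or seg.activity == "absent":
            labels.append(SecondLabel(second=t, activity="absent", persons=0))
            continue

        if seg.activity == "walk":
            if t == seg.start:
                speed = float(seg.params.get("speed", DEFAULT_WALK_SPEED))
                heading = math.radians(float(seg.params.get("heading", 0.0)))
                walk_v = np.array(
                    [speed * math.cos(heading), speed * math.sin(heading)]
                )
                if abs(walk_v[0]) > (x_hi - x_lo) or abs(walk_v[1]) > (y_hi - y_lo):
                    raise ScheduleError(
                        f"walk speed {speed} px/s exceeds the room extent"
                    )
            else:
                # reverse before a step that would cross a margin, so every
                # per-second displacement keeps exactly |v| magnitude
                if not x_lo <= anchor[0] + walk_v[0] <= x_hi:
                    walk_v[0] = -walk_v[0]
                if not y_lo <= anchor[1] + walk_v[1] <= y_hi:
                    walk_v[1] = -walk_v[1]
                anchor = anchor + walk_v

        tpl = skeleton_template(seg.activity, _phase_of(seg, t), seg.params)

        # posture-change ramp: blend from the previous segment's template
        transition = False
        if (
            prev_poseful is not None
            and prev_poseful.end == seg.start
            and t - seg.start < config.ramp_s
        ):
            prev_tpl = skeleton_template(
                prev_poseful.activity, _phase_of(prev_poseful, t), prev_poseful.params
            )
            if _templates_differ(prev_tpl, tpl):
                u = (t - seg.start + 1) / config.ramp_s
                tpl = {
                    p: (
                        (1 - u) * prev_tpl[p][0] + u * tpl[p][0],
                        (1 - u) * prev_tpl[p][1] + u * tpl[p][1],
                    )
                    for p in COCO_PARTS
                }
                transition = True

        if config.noise_sd > 0:
            noise = rng.normal(0.0, config.noise_sd, size=(len(COCO_PARTS), 2))
        else:
            noise = np.zeros((len(COCO_PARTS), 2))
        scores = config.score_model.sample(rng, size=len(COCO_PARTS) + 1)
        overall = float(scores[0])
        persons = 2 if seg.activity == "visitor" else 1
        kps = []
        for i, part in enumerate(COCO_PARTS):
            dx, dy = tpl[part]
            x = float(np.clip(anchor[0] + dx + noise[i, 0], 0.0, width))
            y = float(np.clip(anchor[1] + dy + noise[i, 1], 0.0, height))
            kps.append(Keypoint(part=part, x=x, y=y, score=float(scores[i + 1])))
        frames.append(
            PoseFrame(timestamp=t, score=overall, persons=persons, keypoints=tuple(kps))
        )
        labels.append(
            SecondLabel(
                second=t, activity=seg.activity, persons=persons, transition=transition
            )
        )
    return SimResult(frames=frames, labels=labels)


def expected_channel(activity: str) -> MetricName | None:
    """Delta channel an activity is expected to dominate (None for static)."""
    return {
        "walk": MetricName.POSITIONAL_CHANGE,
        "hand_activity": MetricName.BODY_MOVEMENT,
    }.get(activity)


def minute_ground_truth(
    labels: Sequence[SecondLabel],
) -> dict[int, MetricName]:
    """Expected dominant parameter for each unambiguous minute.

    A minute is unambiguous when all 60 of its seconds carry the same
    single-person activity, none is a transition second, and the activity
    has a defined dominant channel (walk or hand activity).  Static,
    mixed, visitor and transition-straddling minutes are excluded.
    """
    by_minute: dict[int, list[SecondLabel]] = {}
    for lab in labels:
        by_minute.setdefault((lab.second // 60) * 60, []).append(lab)
    truth: dict[int, MetricName] = {}
    for minute, labs in by_minute.items():
        if len(labs) != 60:
            continue
        activities = {l.activity for l in labs}
        if len(activities) != 1:
            continue
        if any(l.transition for l in labs) or any(l.persons != 1 for l in labs):
            continue
        channel = expected_channel(activities.pop())
        if channel is not None:
            truth[minute] = channel
    return truth


def dominant_match_rate(
    minute_summaries,
    truth: Mapping[int, MetricName],
    mapping: Mapping[str, MetricName] = DEFAULT_CHANNEL_MAP,
) -> tuple[int, int]:
    """(matched, total) dominant-channel agreement over unambiguous minutes.

    Each minute's label is the dominant parameter of its per-minute mean
    deltas; a minute in the ground truth without a summary (all frames
    filtered out) counts as unmatched.
    """
    by_minute = {s.minute_start: s for s in minute_summaries}
    matched = 0
    for minute, expected in truth.items():
        s = by_minute.get(minute)
        if s is None:
            continue
        rec = DeltaRecord(
            timestamp=minute,
            d_height=s.mean_d_height,
            d_width=s.mean_d_width,
            d_distance=s.mean_d_distance,
            gap=1,
        )
        if label_dominant(rec, mapping=mapping) == expected:
            matched += 1
    return matched, len(truth)


def demo_schedule(start: int = 0, blocks: int = 4) -> tuple[ActivitySegment, ...]:
    """A repeating 30-minute activity block (default 4 blocks = 2 h).

    Each block: stand 3 min, walk 6 min, sit 3 min, hand activity 6 min,
    lie 3 min, walk 4 min, absent 2 min, stand 3 min.
    """
    pattern = [
        ("stand", 180),
        ("walk", 360),
        ("sit", 180),
        ("hand_activity", 360),
        ("lie", 180),
        ("walk", 240),
        ("absent", 120),
        ("stand", 180),
    ]
    segments = []
    t = start
    for _ in range(blocks):
        for activity, dur in pattern:
            segments.append(ActivitySegment(start=t, end=t + dur, activity=activity))
            t += dur
    return tuple(segments)


def load_config(path) -> SimConfig:
    """Load a simulation config from a JSON or YAML document.

    Top-level keys mirror :class:`SimConfig`: ``resolution``, ``noise_sd``,
    ``seed``, ``ramp_s``, ``score_mean``, ``score_concentration`` and a
    ``schedule`` list of ``{start, end, activity, params?}`` objects.
    """
    with open(path, "r", encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict) or "schedule" not in doc:
        raise ScheduleError(f"{path}: config must be a mapping with a 'schedule' list")
    schedule = tuple(
        ActivitySegment(
            start=int(s["start"]),
            end=int(s["end"]),
            activity=str(s["activity"]),
            params=dict(s.get("params", {})),
        )
        for s in doc["schedule"]
    )
    kwargs: dict = {"schedule": schedule}
    if "resolution" in doc:
        kwargs["resolution"] = tuple(int(v) for v in doc["resolution"])
    for key in ("noise_sd", "seed", "ramp_s"):
        if key in doc:
            kwargs[key] = doc[key]
    if "score_mean" in doc or "score_concentration" in doc:
        kwargs["score_model"] = ScoreModel(
            mean=float(doc.get("score_mean", 0.85)),
            concentration=float(doc.get("score_concentration", 100.0)),
        )
    if "start_anchor" in doc:
        kwargs["start_anchor"] = tuple(float(v) for v in doc["start_anchor"])
    return SimConfig(**kwargs)


def write_labels_csv(labels: Sequence[SecondLabel], path) -> None:
    """Ground-truth export: ``second,activity,persons``."""
    df = pd.DataFrame(
        [(l.second, l.activity, l.persons) for l in labels],
        columns=["second", "activity", "persons"],
    )
    df.to_csv(path, index=False)
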