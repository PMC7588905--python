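"""Pose-map and chart rendering.

Pose maps draw the 17 keypoints, the standard skeleton connectivity and
the bounding box at the stream resolution.  Charts mirror the monitoring
workflow: per-minute line charts of the three evaluating parameters for
one day, and a daily combination chart with bars for the cumulative
channel totals (left axis) and a line for active hours (right axis).

All output is static files (PNG or SVG).  SVG output is byte-stable for a
fixed input: the embedded creation date is stripped and the id-hash salt
pinned.
"""

from __future__ import annotations

import datetime
from typing import Mapping, Sequence

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
from matplotlib.patches import Rectangle

from .aggregation import DailySummary, MinuteSummary
from .features import DEFAULT_CHANNEL_MAP, MetricName, bbox_from_keypoints
from .io_keypoints import PoseFrame

__all__ = [
    "SKELETON_EDGES",
    "render_pose_map",
    "render_minute_chart",
    "render_daily_chart",
]

plt.rcParams["svg.hashsalt"] = "posedelta"

#: Standard 17-keypoint skeleton connectivity.
SKELETON_EDGES: tuple[tuple[str, str], ...] = (
    ("nose", "leftEye"), ("nose", "rightEye"),
    ("leftEye", "leftEar"), ("rightEye", "rightEar"),
    ("leftShoulder", "rightShoulder"),
    ("leftShoulder", "leftElbow"), ("leftElbow", "leftWrist"),
    ("rightShoulder", "rightElbow"), ("rightElbow", "rightWrist"),
    ("leftShoulder", "leftHip"), ("rightShoulder", "rightHip"),
    ("leftHip", "rightHip"),
    ("leftHip", "leftKnee"), ("leftKnee", "leftAnkle"),
    ("rightHip", "rightKnee"), ("rightKnee", "rightAnkle"),
)

_CHANNEL_LABELS = {
    MetricName.POSE_CONVERSION: "pose conversion",
    MetricName.BODY_MOVEMENT: "body movement",
    MetricName.POSITIONAL_CHANGE: "positional changes",
}


def _save(fig, path) -> None:
    # strip the SVG creation date so identical input renders identical bytes
    fig.savefig(path, metadata={"Date": None} if str(path).endswith(".svg") else None)
    plt.close(fig)


def render_pose_map(
    frame: PoseFrame,
    resolution: tuple[int, int],
    path,
    min_kp_score: float = 0.0,
    dpi: int = 100,
) -> None:
    """Draw one frame's keypoints, skeleton and bounding box to a file.

    The raster output has exactly the scene's pixel dimensions.  Frames
    without keypoints cannot be drawn and raise ``ValueError``.
    """
    if not frame.keypoints:
        raise ValueError("cannot render a frame without keypoints")
    width, height = resolution
    fig = plt.figure(figsize=(width / dpi, height / dpi), dpi=dpi)
    ax = fig.add_axes([0, 0, 1, 1])
    ax.set_xlim(0, width)
    ax.set_ylim(height, 0)  # image convention: y down
    ax.set_axis_off()

    pos = {kp.part: (kp.x, kp.y) for kp in frame.keypoints}
    for a, b in SKELETON_EDGES:
        if a in pos and b in pos:
            ax.plot(
                [pos[a][0], pos[b][0]], [pos[a][1], pos[b][1]],
                color="tab:blue", linewidth=1.5,
            )
    xs = [kp.x for kp in frame.keypoints]
    ys = [kp.y for kp in frame.keypoints]
    ax.scatter(xs, ys, s=12, color="tab:red", zorder=3)

    box = bbox_from_keypoints(frame.keypoints, min_kp_score)
    ax.add_patch(
        Rectangle(
            (box.x_min, box.y_min), box.width, box.height,
            fill=False, edgecolor="tab:green", linewidth=1.2,
        )
    )
    _save(fig, path)


def render_minute_chart(
    summaries: Sequence[MinuteSummary],
    path,
    mapping: Mapping[str, MetricName] = DEFAULT_CHANNEL_MAP,
    title: str | None = None,
) -> None:
    """Per-minute line chart of the three evaluating parameters.

    The x axis is clock time; minutes without data appear as gaps, never
    as zeros (no data means the person was absent, not still).
    """
    if not summaries:
        raise ValueError("no minute summaries to plot")
    times = [datetime.datetime(1970, 1, 1) + datetime.timedelta(seconds=s.minute_start)
             for s in summaries]
    fig, ax = plt.subplots(figsize=(10, 4))
    for channel, metric in mapping.items():
        values = [s.channel_mean(channel) for s in summaries]
        ax.plot(times, values, label=_CHANNEL_LABELS[metric], linewidth=1.0)
    ax.set_xlabel("time")
    ax.set_ylabel("mean change per minute (px)")
    if title:
        ax.set_title(title)
    ax.legend(loc="upper right")
    fig.autofmt_xdate()
    fig.tight_layout()
    _save(fig, path)


def render_daily_chart(
    summaries: Sequence[DailySummary],
    path,
    mapping: Mapping[str, MetricName] = DEFAULT_CHANNEL_MAP,
    title: str | None = None,
) -> None:
    """Daily combination chart: channel totals as bars, active hours as a line.

    Dual axes: cumulative coordinate change (px) on the left, total active
    time per day (h) on the right.
    """
    if not summaries:
        raise ValueError("no daily summaries to plot")
    dates = [s.date.isoformat() for s in summaries]
    n = len(summaries)
    fig, ax = plt.subplots(figsize=(max(6, 1.2 * n), 4.5))
    width = 0.25
    totals_by_channel = {
        "d_height": [s.total_d_height for s in summaries],
        "d_width": [s.total_d_width for s in summaries],
        "d_distance": [s.total_d_distance for s in summaries],
    }
    for i, (channel, metric) in enumerate(mapping.items()):
        offsets = [j + (i - 1) * width for j in range(n)]
        ax.bar(offsets, totals_by_channel[channel], width=width,
               label=_CHANNEL_LABELS[metric])
    ax.set_xticks(range(n))
    ax.set_xticklabels(dates, rotation=30, ha="right")
    ax.set_ylabel("cumulative change (px)")
    ax2 = ax.twinx()
    ax2.plot(range(n), [s.active_hours for s in summaries],
             color="black", marker="o", label="active hours")
    ax2.set_ylabel("total time hours")
    ax2.set_ylim(0, 24)
    handles1, labels1 = ax.get_legend_handles_labels()
    handles2, labels2 = ax2.get_legend_handles_labels()
    ax.legend(handles1 + handles2, labels1 + labels2, loc="upper left", fontsize=8)
    if title:
        ax.set_title(title)
    fig.tight_layout()
    _save(fig, path)
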