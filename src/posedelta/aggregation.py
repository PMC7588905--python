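"""Minute- and day-level summaries of per-second delta records.

Per-minute values are the evaluating data of the monitoring method: the
arithmetic mean of each delta channel over all records in a wall-clock
minute (a simple moving average of window 60 s sampled once per minute).
Day-level summaries accumulate the per-second deltas into daily totals and
convert the count of valid stored frames into "active hours" — the total
time per day for which postural data exists.
"""

from __future__ import annotations

import datetime
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .features import DeltaRecord, FilterPolicy, frame_is_valid
from .io_keypoints import PoseFrame

__all__ = [
    "MinuteSummary",
    "DailySummary",
    "summarize_minutes",
    "summarize_days",
    "presence_intervals",
    "write_minutes_csv",
    "write_daily_csv",
]

_SECONDS_PER_DAY = 86400


@dataclass(frozen=True)
class MinuteSummary:
    """Mean delta per channel over one wall-clock minute.

    Minutes without any record are absent from the output, never
    zero-filled: a zero would conflate "present but still" with "absent"
    (absent-person seconds are never stored in the first place).
    """

    minute_start: int
    mean_d_height: float
    mean_d_width: float
    mean_d_distance: float
    n_records: int

    def channel_mean(self, name: str) -> float:
        return {
            "d_height": self.mean_d_height,
            "d_width": self.mean_d_width,
            "d_distance": self.mean_d_distance,
        }[name]


@dataclass(frozen=True)
class DailySummary:
    """Cumulative totals and active time for one calendar day."""

    date: datetime.date
    total_d_height: float
    total_d_width: float
    total_d_distance: float
    active_hours: float
    n_frames: int


def _minute_of(ts: int) -> int:
    return (ts // 60) * 60


def _date_of(ts: int) -> datetime.date:
    # civil day of the timestamps' own clock; no timezone arithmetic
    return (datetime.datetime(1970, 1, 1) + datetime.timedelta(seconds=ts)).date()


def summarize_minutes(
    records: Sequence[DeltaRecord], sliding: bool = False
) -> list[MinuteSummary]:
    """Partition records into minute windows and average each channel.

    With ``sliding=False`` (default) the windows are non-overlapping
    ``[t, t+60)`` intervals aligned to the wall-clock minute grid, one
    summary per populated minute.  With ``sliding=True`` a trailing-window
    variant is returned: one summary per record second, averaging the
    records in ``(t-60, t]`` and reported at ``minute_start = t - 59``.
    """
    if not records:
        return []
    out: list[MinuteSummary] = []
    if sliding:
        for rec in records:
            window = [r for r in records if rec.timestamp - 60 < r.timestamp <= rec.timestamp]
            out.append(_mean_summary(rec.timestamp - 59, window))
        return out
    current_minute: int | None = None
    bucket: list[DeltaRecord] = []
    for rec in records:
        minute = _minute_of(rec.timestamp)
        if current_minute is None:
            current_minute = minute
        if minute != current_minute:
            out.append(_mean_summary(current_minute, bucket))
            current_minute, bucket = minute, []
        bucket.append(rec)
    out.append(_mean_summary(current_minute, bucket))
    return out


def _mean_summary(minute_start: int, bucket: Sequence[DeltaRecord]) -> MinuteSummary:
    n = len(bucket)
    return MinuteSummary(
        minute_start=minute_start,
        mean_d_height=sum(r.d_height for r in bucket) / n,
        mean_d_width=sum(r.d_width for r in bucket) / n,
        mean_d_distance=sum(r.d_distance for r in bucket) / n,
        n_records=n,
    )


def summarize_days(
    frames: Sequence[PoseFrame],
    records: Sequence[DeltaRecord],
    policy: FilterPolicy = FilterPolicy(),
) -> list[DailySummary]:
    """Per-calendar-day channel totals and active hours.

    ``active_hours`` is the count of frames passing the policy that day
    divided by 3600 — each stored valid frame stands for one monitored
    second.  Days without any valid frame are absent from the output.
    """
    frame_counts: dict[datetime.date, int] = {}
    for frame in frames:
        if frame_is_valid(frame, policy):
            day = _date_of(frame.timestamp)
            frame_counts[day] = frame_counts.get(day, 0) + 1
    totals: dict[datetime.date, list[float]] = {}
    for rec in records:
        day = _date_of(rec.timestamp)
        t = totals.setdefault(day, [0.0, 0.0, 0.0])
        t[0] += rec.d_height
        t[1] += rec.d_width
        t[2] += rec.d_distance
    out = []
    for day in sorted(frame_counts):
        t = totals.get(day, [0.0, 0.0, 0.0])
        out.append(
            DailySummary(
                date=day,
                total_d_height=t[0],
                total_d_width=t[1],
                total_d_distance=t[2],
                active_hours=frame_counts[day] / 3600.0,
                n_frames=frame_counts[day],
            )
        )
    return out


def presence_intervals(
    frames: Sequence[PoseFrame],
    policy: FilterPolicy = FilterPolicy(),
    min_gap: int = 300,
) -> list[tuple[int, int]]:
    """Maximal runs of valid frames separated by gaps longer than ``min_gap``.

    Returns ``(start, end)`` timestamp pairs (first/last frame of each
    run).  These runs underlie waking / break / sleep inference: a long
    gap means the person was absent (or unobservable) for that span.
    """
    intervals: list[tuple[int, int]] = []
    run_start: int | None = None
    last_ts: int | None = None
    for frame in frames:
        if not frame_is_valid(frame, policy):
            continue
        if last_ts is not None and frame.timestamp - last_ts > min_gap:
            intervals.append((run_start, last_ts))
            run_start = None
        if run_start is None:
            run_start = frame.timestamp
        last_ts = frame.timestamp
    if run_start is not None:
        intervals.append((run_start, last_ts))
    return intervals


def write_minutes_csv(summaries: Iterable[MinuteSummary], path) -> None:
    df = pd.DataFrame(
        [
            (s.minute_start, s.mean_d_height, s.mean_d_width, s.mean_d_distance, s.n_records)
            for s in summaries
        ],
        columns=["minute_start", "mean_d_height", "mean_d_width", "mean_d_distance", "n_records"],
    )
    df.to_csv(path, index=False)


def write_daily_csv(summaries: Iterable[DailySummary], path) -> None:
    df = pd.DataFrame(
        [
            (
                s.date.isoformat(),
                s.total_d_height,
                s.total_d_width,
                s.total_d_distance,
                s.active_hours,
                s.n_frames,
            )
            for s in summaries
        ],
        columns=[
            "date",
            "total_d_height",
            "total_d_width",
            "total_d_distance",
            "active_hours",
            "n_frames",
        ],
    )
    df.to_csv(path, index=False)
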