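"""Bounding-box agreement between predicted and reference keypoint sets.

For every image the predicted box (from an estimator's keypoints) is
compared against the reference box (from ground-truth annotations) with
exactly the same three metrics used on monitored streams: absolute height
difference, absolute width difference, and center-to-center distance.  The
per-image difference values K are then binned into ranges (default
K <= 10, 10 < K <= 30, K > 30 pixels) and reported as percentages of all
compared images per channel.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .features import BoundingBox, delta_metrics

__all__ = [
    "CHANNELS",
    "DifferenceTriple",
    "BinReport",
    "difference_triple",
    "compare_sets",
    "bin_report",
    "format_report",
    "write_report_csv",
]

CHANNELS = ("k_height", "k_width", "k_distance")


@dataclass(frozen=True)
class DifferenceTriple:
    """Per-image difference values K between predicted and reference box."""

    image_id: str
    k_height: float
    k_width: float
    k_distance: float

    def channel(self, name: str) -> float:
        return {"k_height": self.k_height, "k_width": self.k_width,
                "k_distance": self.k_distance}[name]


@dataclass(frozen=True)
class BinReport:
    """Percentage of images per difference range, per channel.

    ``percentages[channel]`` is ``(K <= e1, e1 < K <= e2, K > e2)``, each
    rounded to two decimals; ``counts`` holds the raw bin counts.
    """

    edges: tuple[float, float]
    n_images: int
    counts: Mapping[str, tuple[int, int, int]]
    percentages: Mapping[str, tuple[float, float, float]]


def difference_triple(
    pred: BoundingBox, ref: BoundingBox, image_id: str = ""
) -> DifferenceTriple:
    """Difference values K for one image (same formulas as stream deltas)."""
    k_h, k_w, k_d = delta_metrics(ref, pred)
    return DifferenceTriple(image_id=image_id, k_height=k_h, k_width=k_w, k_distance=k_d)


def compare_sets(
    pred: Mapping[str, BoundingBox],
    ref: Mapping[str, BoundingBox],
    mode: str = "paired",
) -> list[DifferenceTriple]:
    """Compare predicted against reference boxes keyed by image id.

    ``mode="paired"`` (default) compares each image's predicted box with
    the reference box of the same image.  ``mode="sequential"`` is an
    alternative protocol kept for completeness: both sets are read as a
    pseudo-sequence in image-id order, the per-pair change metrics are
    computed within each source, and K is the absolute difference of those
    metrics between sources.

    Any image id present in one set but not the other is an error — images
    are never silently dropped.
    """
    pred_ids, ref_ids = set(pred), set(ref)
    if pred_ids != ref_ids:
        only_pred = sorted(pred_ids - ref_ids)[:5]
        only_ref = sorted(ref_ids - pred_ids)[:5]
        raise ValueError(
            f"image ids do not match (only in predicted: {only_pred}, "
            f"only in reference: {only_ref})"
        )
    ids = sorted(pred_ids)
    if mode == "paired":
        return [difference_triple(pred[i], ref[i], image_id=i) for i in ids]
    if mode == "sequential":
        triples = []
        for a, b in zip(ids, ids[1:]):
            ph, pw, pd_ = delta_metrics(pred[a], pred[b])
            rh, rw, rd = delta_metrics(ref[a], ref[b])
            triples.append(
                DifferenceTriple(
                    image_id=b,
                    k_height=abs(ph - rh),
                    k_width=abs(pw - rw),
                    k_distance=abs(pd_ - rd),
                )
            )
        return triples
    raise ValueError(f"unknown mode {mode!r}")


def bin_report(
    triples: Sequence[DifferenceTriple], edges: tuple[float, float] = (10.0, 30.0)
) -> BinReport:
    """Bin each image's K per channel and report percentages of the total.

    Bins are closed on the upper edge: ``K <= e1``, ``e1 < K <= e2``,
    ``K > e2``; every image falls in exactly one bin per channel.
    """
    e1, e2 = edges
    if not e1 < e2:
        raise ValueError(f"edges must be increasing, got {edges}")
    if not triples:
        raise ValueError("bin_report needs at least one difference triple")
    n = len(triples)
    counts: dict[str, tuple[int, int, int]] = {}
    percentages: dict[str, tuple[float, float, float]] = {}
    for ch in CHANNELS:
        low = sum(1 for t in triples if t.channel(ch) <= e1)
        mid = sum(1 for t in triples if e1 < t.channel(ch) <= e2)
        high = n - low - mid
        counts[ch] = (low, mid, high)
        percentages[ch] = tuple(round(100.0 * c / n, 2) for c in (low, mid, high))
    return BinReport(edges=(e1, e2), n_images=n, counts=counts, percentages=percentages)


def format_report(report: BinReport) -> str:
    """Pretty text table: one row per difference range, one column per channel."""
    e1, e2 = report.edges
    rows = [f"K <= {e1:g}", f"{e1:g} < K <= {e2:g}", f"K > {e2:g}"]
    header = f"{'Difference Value (K)':<22}" + "".join(
        f"{ch[2:].capitalize():>12}" for ch in CHANNELS
    )
    lines = [header]
    for i, label in enumerate(rows):
        cells = "".join(f"{report.percentages[ch][i]:>11.2f}%" for ch in CHANNELS)
        lines.append(f"{label:<22}{cells}")
    lines.append(f"n_images = {report.n_images}")
    return "\n".join(lines)


def write_report_csv(report: BinReport, path) -> None:
    e1, e2 = report.edges
    df = pd.DataFrame(
        {
            "range": [f"K <= {e1:g}", f"{e1:g} < K <= {e2:g}", f"K > {e2:g}"],
            **{ch: list(report.percentages[ch]) for ch in CHANNELS},
        }
    )
    df.to_csv(path, index=False)
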