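"""Calibrated movement speeds and behavioural-category tallies.

Converts pixel tracks to cm-scale speeds per frame interval and classifies
each interval as resting (0 to < 0.4 cm/h), slow (0.4-4 cm/h) or fast
(> 4 cm/h). A "detection" in the per-flume tallies is one classified grazer
x frame-interval; intervals lost to missed detections are not counted.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass

import pandas as pd

from .linking import Track
from .scene import RESTING_MAX, SLOW_MAX

CATEGORIES = ("resting", "slow", "fast")


def classify_speed(speed_cm_per_h: float) -> str:
    """Category of a non-negative speed: resting [0, 0.4), slow [0.4, 4],
    fast (4, inf). The 0.4 boundary belongs to slow (strict inequality for
    resting)."""
    if speed_cm_per_h < 0:
        raise ValueError("speed must be non-negative")
    if speed_cm_per_h < RESTING_MAX:
        return "resting"
    if speed_cm_per_h <= SLOW_MAX:
        return "slow"
    return "fast"


@dataclass(frozen=True)
class MovementRecord:
    track_id: int
    frame_from: int
    frame_to: int
    elapsed_s: float
    displacement_cm: float
    speed_cm_per_h: float
    category: str
    flume_id: str = ""


def compute_speeds(
    track: Track,
    px_per_cm: float,
    frame_interval_s: float,
    flume_id: str = "",
    smooth_window: int = 1,
) -> list[MovementRecord]:
    """One record per consecutive pair of observed entries.

    Displacement is the Euclidean distance in px over px_per_cm; intervals
    spanning gaps use the total elapsed time between the two observations,
    so a grazer lost for three frames contributes one record over four frame
    intervals. Tracks with fewer than two observations yield no records.

    ``smooth_window`` (odd, default 1 = off) applies a centred moving
    average to the observed positions before differencing, for recordings
    where centroid jitter is comparable to the per-interval displacement.
    """
    if px_per_cm <= 0:
        raise ValueError("px_per_cm must be positive")
    if frame_interval_s <= 0:
        raise ValueError("frame_interval_s must be positive")
    if smooth_window < 1 or smooth_window % 2 == 0:
        raise ValueError("smooth_window must be a positive odd integer")
    obs = track.observed_entries
    xs = [e.x for e in obs]
    ys = [e.y for e in obs]
    if smooth_window > 1 and len(obs) > 1:
        half = smooth_window // 2
        n = len(obs)
        xs = [sum(xs[max(0, i - half):min(n, i + half + 1)]) / (min(n, i + half + 1) - max(0, i - half)) for i in range(n)]
        ys = [sum(ys[max(0, i - half):min(n, i + half + 1)]) / (min(n, i + half + 1) - max(0, i - half)) for i in range(n)]
    records = []
    for k, (a, b) in enumerate(zip(obs, obs[1:])):
        elapsed = (b.frame - a.frame) * frame_interval_s
        disp = math.hypot(xs[k + 1] - xs[k], ys[k + 1] - ys[k]) / px_per_cm
        speed = disp / (elapsed / 3600.0)
        records.append(
            MovementRecord(
                track_id=track.track_id,
                frame_from=a.frame,
                frame_to=b.frame,
                elapsed_s=elapsed,
                displacement_cm=disp,
                speed_cm_per_h=speed,
                category=classify_speed(speed),
                flume_id=flume_id,
            )
        )
    return records


@dataclass(frozen=True)
class CategoryCounts:
    flume_id: str
    treatment: str
    resting: int
    slow: int
    fast: int

    @property
    def total(self) -> int:
        return self.resting + self.slow + self.fast


def tally_categories(
    records: list[MovementRecord],
    treatments: dict[str, str] | None = None,
) -> list[CategoryCounts]:
    """Per-flume counts of classified intervals per category.

    ``treatments`` optionally maps flume_id to a treatment label for the
    output rows. The grand total over categories equals the number of input
    records.
    """
    treatments = treatments or {}
    by_flume: dict[str, Counter] = {}
    for r in records:
        by_flume.setdefault(r.flume_id, Counter())[r.category] += 1
    return [
        CategoryCounts(
            flume_id=fid,
            treatment=treatments.get(fid, ""),
            resting=counts.get("resting", 0),
            slow=counts.get("slow", 0),
            fast=counts.get("fast", 0),
        )
        for fid, counts in sorted(by_flume.items())
    ]


def records_to_table(records: list[MovementRecord]) -> pd.DataFrame:
    rows = [
        {
            "flume": r.flume_id,
            "track_id": r.track_id,
            "frame_from": r.frame_from,
            "frame_to": r.frame_to,
            "elapsed_s": r.elapsed_s,
            "displacement_cm": r.displacement_cm,
            "speed_cm_per_h": r.speed_cm_per_h,
            "category": r.category,
        }
        for r in records
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "flume",
            "track_id",
            "frame_from",
            "frame_to",
            "elapsed_s",
            "displacement_cm",
            "speed_cm_per_h",
            "category",
        ],
    )


def counts_to_table(counts: list[CategoryCounts]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "flume": c.flume_id,
                "treatment": c.treatment,
                "resting": c.resting,
                "slow": c.slow,
                "fast": c.fast,
            }
            for c in counts
        ],
        columns=["flume", "treatment", "resting", "slow", "fast"],
    )
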