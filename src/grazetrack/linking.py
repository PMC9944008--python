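"""Identity linking of per-frame detections into per-grazer tracks.

The field rule "match objects with the shortest Euclidean distance in
consecutive frames" is implemented as a globally optimal bipartite
assignment per frame (Hungarian algorithm), which coincides with the
pairwise rule for well-separated slow movers and stays well-defined under
ties and conflicts. Missed detections leave explicit gaps (no
interpolation); a track's gating radius grows linearly with the length of
its current gap so reappearing grazers are recaptured.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .detect import Detection

_BIG = 1e12


@dataclass(frozen=True)
class LinkParams:
    n_expected: int = 8
    max_step_px: float = 10.0
    max_gap_frames: int = 20

    def __post_init__(self) -> None:
        if self.n_expected < 1:
            raise ValueError("n_expected must be >= 1")
        if self.max_step_px <= 0:
            raise ValueError("max_step_px must be > 0")
        if self.max_gap_frames < 0:
            raise ValueError("max_gap_frames must be >= 0")


def suggested_max_step_px(max_speed_cm_per_h: float, frame_interval_s: float, px_per_cm: float) -> float:
    """Gating default: three times the expected per-interval displacement of
    the fastest mover (a proxy for its upper-percentile step), floored at
    2 px so sub-pixel movers still gate sensibly."""
    step = max_speed_cm_per_h * (frame_interval_s / 3600.0) * px_per_cm
    return max(3.0 * step, 2.0)


@dataclass
class TrackEntry:
    frame: int
    x: float
    y: float
    observed: bool


@dataclass
class Track:
    """One grazer's identity-linked position sequence.

    Unobserved frames are stored as gap entries with NaN coordinates; the
    last observed position is what assignment gates against. ``seed_xy`` is
    an optional prior position used before the first detection.
    """

    track_id: int
    entries: list[TrackEntry] = field(default_factory=list)
    seed_xy: tuple[float, float] | None = None

    @property
    def observed_entries(self) -> list[TrackEntry]:
        return [e for e in self.entries if e.observed]

    @property
    def last_known_position(self) -> tuple[float, float] | None:
        for e in reversed(self.entries):
            if e.observed:
                return (e.x, e.y)
        return self.seed_xy

    @property
    def frames_since_seen(self) -> int:
        """Length of the current trailing gap (0 right after an observation)."""
        run = 0
        for e in reversed(self.entries):
            if e.observed:
                break
            run += 1
        return run

    def append_observation(self, frame: int, x: float, y: float) -> None:
        self._check_frame(frame)
        self.entries.append(TrackEntry(frame, x, y, True))

    def append_gap(self, frame: int) -> None:
        self._check_frame(frame)
        self.entries.append(TrackEntry(frame, math.nan, math.nan, False))

    def _check_frame(self, frame: int) -> None:
        if self.entries and frame <= self.entries[-1].frame:
            raise ValueError("frame indices must be strictly increasing")


@dataclass(frozen=True)
class Assignment:
    """Result of one frame's track <-> detection matching."""

    matches: tuple[tuple[int, int], ...]  # (track_id, detection index)
    unmatched_track_ids: tuple[int, ...]
    unmatched_detections: tuple[int, ...]
    total_cost: float


def assign_frame(
    tracks: list[Track], detections: list[Detection], params: LinkParams
) -> Assignment:
    """One-to-one assignment minimising total Euclidean distance.

    Pairs beyond a track's gate (max_step_px x (trailing gap + 1), gap
    capped at max_gap_frames) are infeasible; unmatched tracks gain a gap
    and surplus detections are reported unmatched. Ties are broken towards
    lower track ids, then lexicographically smaller detection coordinates.
    """
    if len(tracks) > params.n_expected:
        raise ValueError("more tracks than expected grazers")
    positions = [t.last_known_position for t in tracks]
    active = [i for i, p in enumerate(positions) if p is not None]
    # lexicographic detection order for deterministic tie-breaking
    det_order = sorted(range(len(detections)), key=lambda j: (detections[j].x_px, detections[j].y_px))
    if not active or not detections:
        return Assignment(
            matches=(),
            unmatched_track_ids=tuple(t.track_id for t in tracks),
            unmatched_detections=tuple(range(len(detections))),
            total_cost=0.0,
        )
    cost = np.full((len(active), len(detections)), _BIG)
    for r, i in enumerate(active):
        x0, y0 = positions[i]
        gap = min(tracks[i].frames_since_seen, params.max_gap_frames)
        gate = params.max_step_px * (gap + 1)
        for c, j in enumerate(det_order):
            d = math.hypot(detections[j].x_px - x0, detections[j].y_px - y0)
            if d <= gate:
                # epsilon tie-breakers: lower track_id, then earlier in
                # lexicographic detection order
                cost[r, c] = d + 1e-7 * tracks[i].track_id + 1e-9 * c
    rows, cols = linear_sum_assignment(cost)
    matches = []
    total = 0.0
    matched_tracks, matched_dets = set(), set()
    for r, c in zip(rows, cols):
        if cost[r, c] >= _BIG:
            continue
        i, j = active[r], det_order[c]
        x0, y0 = positions[i]
        total += math.hypot(detections[j].x_px - x0, detections[j].y_px - y0)
        matches.append((tracks[i].track_id, j))
        matched_tracks.add(i)
        matched_dets.add(j)
    return Assignment(
        matches=tuple(matches),
        unmatched_track_ids=tuple(
            t.track_id for i, t in enumerate(tracks) if i not in matched_tracks
        ),
        unmatched_detections=tuple(j for j in range(len(detections)) if j not in matched_dets),
        total_cost=total,
    )


def link_sequence(
    detections_per_frame: list[list[Detection]],
    params: LinkParams,
    initial_positions: list[tuple[float, float]] | None = None,
) -> list[Track]:
    """Link a temporally ordered detection sequence into n_expected tracks.

    Track ids 0..n-1 are fixed at initialisation: from ``initial_positions``
    if given, otherwise from the first frame's detections sorted
    lexicographically. If fewer than n_expected objects appear initially,
    the remaining tracks start at their first unmatched detection.
    """
    tracks: list[Track] = []
    if initial_positions is not None:
        if len(initial_positions) > params.n_expected:
            raise ValueError("more initial positions than expected grazers")
        tracks = [Track(track_id=i, seed_xy=(float(x), float(y))) for i, (x, y) in enumerate(initial_positions)]

    for frame_idx, dets in enumerate(detections_per_frame):
        if not tracks and dets:
            ordered = sorted(dets, key=lambda d: (d.x_px, d.y_px))[: params.n_expected]
            for i, d in enumerate(ordered):
                tr = Track(track_id=i)
                tr.append_observation(frame_idx, d.x_px, d.y_px)
                tracks.append(tr)
            continue
        assignment = assign_frame(tracks, dets, params)
        matched = dict(assignment.matches)
        by_id = {t.track_id: t for t in tracks}
        for tid, j in matched.items():
            by_id[tid].append_observation(frame_idx, dets[j].x_px, dets[j].y_px)
        for tid in assignment.unmatched_track_ids:
            by_id[tid].append_gap(frame_idx)
        # surplus detections open new tracks while slots remain
        for j in assignment.unmatched_detections:
            if len(tracks) >= params.n_expected:
                break
            tr = Track(track_id=len(tracks))
            tr.append_observation(frame_idx, dets[j].x_px, dets[j].y_px)
            tracks.append(tr)
    return tracks


def tracks_to_table(tracks: list[Track]) -> pd.DataFrame:
    rows = [
        {
            "track_id": t.track_id,
            "frame": e.frame,
            "x_px": e.x,
            "y_px": e.y,
            "observed": e.observed,
        }
        for t in tracks
        for e in t.entries
    ]
    return pd.DataFrame(rows, columns=["track_id", "frame", "x_px", "y_px", "observed"])


def table_to_tracks(table: pd.DataFrame) -> list[Track]:
    tracks = []
    for tid, grp in table.groupby("track_id", sort=True):
        tr = Track(track_id=int(tid))
        for row in grp.sort_values("frame").itertuples(index=False):
            if bool(row.observed):
                tr.append_observation(int(row.frame), float(row.x_px), float(row.y_px))
            else:
                tr.append_gap(int(row.frame))
        tracks.append(tr)
    return tracks


def identity_agreement(tracks: list[Track], truth_positions_px: np.ndarray) -> float:
    """Fraction of observed (frame, track) entries lying closest to the same
    ground-truth grazer that the track started on.

    ``truth_positions_px`` has shape (n_frames, n_grazers, 2) in pixel
    coordinates. Each track is mapped to the grazer nearest its first
    observation; an entry agrees when that same grazer is its nearest truth
    position at the entry's frame.
    """
    total = 0
    agree = 0
    for tr in tracks:
        obs = tr.observed_entries
        if not obs:
            continue
        first = obs[0]
        d0 = np.hypot(
            truth_positions_px[first.frame, :, 0] - first.x,
            truth_positions_px[first.frame, :, 1] - first.y,
        )
        mapped = int(np.argmin(d0))
        for e in obs:
            d = np.hypot(
                truth_positions_px[e.frame, :, 0] - e.x,
                truth_positions_px[e.frame, :, 1] - e.y,
            )
            total += 1
            if int(np.argmin(d)) == mapped:
                agree += 1
    return agree / total if total else float("nan")
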