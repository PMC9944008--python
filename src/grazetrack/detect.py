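"""Colour-marker detection: RGB matching and blob extraction.

Each grazer carries a pink marker; detection is plain colour matching (no
learning, no background model) followed by connected-component extraction
with sub-pixel centroids, mirroring how slow benthic grazers are located in
time-lapse footage.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage import measure


@dataclass(frozen=True)
class ColourSpec:
    """Target colour and matching tolerance.

    ``mode`` selects the distance criterion: ``"euclidean"`` compares the
    Euclidean RGB distance against ``tolerance``; ``"per_channel"`` requires
    every channel's absolute deviation to be within ``tolerance``.
    """

    target_rgb: tuple[int, int, int]
    tolerance: float = 60.0
    mode: str = "euclidean"

    def __post_init__(self) -> None:
        if self.tolerance < 0:
            raise ValueError("tolerance must be >= 0")
        if any(not 0 <= c <= 255 for c in self.target_rgb):
            raise ValueError("target_rgb channels must be in [0, 255]")
        if self.mode not in ("euclidean", "per_channel"):
            raise ValueError(f"unknown mode {self.mode!r}")


@dataclass(frozen=True)
class Detection:
    """One colour blob: sub-pixel centroid (pixel-index coordinates) and size."""

    frame_index: int
    x_px: float
    y_px: float
    pixel_count: int


def match_colour(frame: np.ndarray, spec: ColourSpec) -> np.ndarray:
    """Boolean mask of pixels matching the colour spec, same H x W as frame."""
    frame = np.asarray(frame)
    if frame.ndim != 3 or frame.shape[2] != 3:
        raise ValueError("frame must be an H x W x 3 RGB raster")
    if frame.size == 0:
        raise ValueError("frame must be non-empty")
    diff = frame.astype(np.float64) - np.asarray(spec.target_rgb, dtype=np.float64)
    if spec.mode == "euclidean":
        return np.sqrt((diff**2).sum(axis=2)) <= spec.tolerance
    return np.abs(diff).max(axis=2) <= spec.tolerance


def extract_blobs(
    mask: np.ndarray,
    min_blob_px: int = 1,
    max_blob_px: int | None = None,
    frame_index: int = 0,
) -> list[Detection]:
    """Connected components (8-connectivity) of a boolean mask as detections.

    Components with pixel counts outside [min_blob_px, max_blob_px] are
    dropped. Centroids are arithmetic means of member pixel indices
    (sub-pixel). Detections are sorted by pixel count descending, then by
    centroid x, then y.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        return []
    labels = measure.label(mask, connectivity=2)
    dets = []
    for region in measure.regionprops(labels):
        n = int(region.area)
        if n < min_blob_px:
            continue
        if max_blob_px is not None and n > max_blob_px:
            continue
        cy, cx = region.centroid
        dets.append(Detection(frame_index=frame_index, x_px=float(cx), y_px=float(cy), pixel_count=n))
    dets.sort(key=lambda d: (-d.pixel_count, d.x_px, d.y_px))
    return dets


def default_blob_limits(marker_radius_px: float) -> tuple[int, int]:
    """Size gate around the expected marker disc area: [25%, 400%] of
    pi r^2, rejecting specks and merged glare."""
    area = math.pi * marker_radius_px**2
    return max(1, int(round(0.25 * area))), max(1, int(round(4.0 * area)))


def detect_frame(
    frame: np.ndarray,
    spec: ColourSpec,
    min_blob_px: int = 1,
    max_blob_px: int | None = None,
    frame_index: int = 0,
) -> list[Detection]:
    """Convenience: colour match then blob extraction for one frame."""
    return extract_blobs(match_colour(frame, spec), min_blob_px, max_blob_px, frame_index)


def detect_sequence(
    frames: np.ndarray,
    spec: ColourSpec,
    min_blob_px: int = 1,
    max_blob_px: int | None = None,
) -> list[list[Detection]]:
    """Detect on every frame of a (n, H, W, 3) stack."""
    return [
        detect_frame(frames[t], spec, min_blob_px, max_blob_px, frame_index=t)
        for t in range(frames.shape[0])
    ]


def detections_to_table(per_frame: list[list[Detection]]) -> pd.DataFrame:
    rows = [
        {"frame": d.frame_index, "x_px": d.x_px, "y_px": d.y_px, "pixel_count": d.pixel_count}
        for dets in per_frame
        for d in dets
    ]
    return pd.DataFrame(rows, columns=["frame", "x_px", "y_px", "pixel_count"])


def table_to_detections(table: pd.DataFrame, n_frames: int | None = None) -> list[list[Detection]]:
    """Inverse of :func:`detections_to_table` (frames without detections get
    empty lists)."""
    if n_frames is None:
        n_frames = int(table["frame"].max()) + 1 if len(table) else 0
    per_frame: list[list[Detection]] = [[] for _ in range(n_frames)]
    for row in table.itertuples(index=False):
        per_frame[int(row.frame)].append(
            Detection(int(row.frame), float(row.x_px), float(row.y_px), int(row.pixel_count))
        )
    return per_frame
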