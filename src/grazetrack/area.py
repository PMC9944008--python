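"""Grazed-area quantification with pixel -> cm^2 calibration.

Bare ceramic tile is brighter than intact biofilm, so grazed substrate is
segmented by luminance difference against an intact-biofilm baseline (with
an Otsu fallback when no threshold is supplied), restricted to the tile
substrate, with grazer-marker pixels excluded before thresholding and small
speckle components removed. Pixel counts convert to cm^2 through the scale
calibrated from the known tile dimensions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import distance_transform_edt
from skimage import morphology
from skimage.color import rgb2gray
from skimage.filters import threshold_otsu

from .detect import ColourSpec, match_colour
from .scene import SceneConfig

# luminance contrasts below this (on the 0-1 scale) are treated as "no
# grazing anywhere" by the Otsu fallback rather than split into noise classes
_MIN_CONTRAST = 0.05


def calibrate_scale(tile_side_px: float, tile_side_cm: float = 2.3) -> float:
    """px_per_cm from the measured pixel side length of a known tile."""
    if tile_side_px <= 0 or tile_side_cm <= 0:
        raise ValueError("tile side lengths must be positive")
    return tile_side_px / tile_side_cm


def tile_total_area(n_tiles: int, tile_side_cm: float = 2.3) -> float:
    """Total substrate area (cm^2) of n square tiles."""
    if n_tiles < 0:
        raise ValueError("n_tiles must be >= 0")
    return n_tiles * tile_side_cm**2


@dataclass(frozen=True)
class Calibration:
    """Pixel scale plus the substrate mask it applies to."""

    px_per_cm: float
    tile_mask: np.ndarray
    tile_side_cm: float = 2.3

    def __post_init__(self) -> None:
        if self.px_per_cm <= 0:
            raise ValueError("px_per_cm must be positive")

    @property
    def total_substrate_cm2(self) -> float:
        return float(self.tile_mask.sum()) / self.px_per_cm**2

    @classmethod
    def from_scene(cls, scene: SceneConfig) -> "Calibration":
        return cls(px_per_cm=scene.px_per_cm, tile_mask=scene.tile_mask(), tile_side_cm=scene.tile_side_cm)


def segment_grazed(
    frame: np.ndarray,
    baseline: np.ndarray | float,
    calib: Calibration,
    threshold: float | None = None,
    marker_spec: ColourSpec | None = None,
    min_component_px: int = 4,
) -> np.ndarray:
    """Boolean grazed mask of one frame.

    ``baseline`` is either an intact-biofilm RGB reference frame or a scalar
    biofilm luminance on the 0-1 scale. Substrate pixels whose luminance
    exceeds the baseline by more than ``threshold`` (bare tile is brighter
    than biofilm) are grazed; with ``threshold=None`` an Otsu threshold on
    the luminance difference is used, returning an empty mask when the
    difference image has essentially no contrast. Marker pixels (matched and
    slightly dilated) are excluded before thresholding and then filled from
    the surrounding segmentation, since a grazer hides the substrate
    directly beneath it.
    """
    frame = np.asarray(frame)
    if frame.ndim != 3 or frame.shape[2] != 3:
        raise ValueError("frame must be an H x W x 3 RGB raster")
    if frame.shape[:2] != calib.tile_mask.shape:
        raise ValueError("frame and tile mask dimensions differ")
    lum = rgb2gray(frame)
    if np.isscalar(baseline):
        diff = lum - float(baseline)
    else:
        baseline = np.asarray(baseline)
        if baseline.shape[:2] != frame.shape[:2]:
            raise ValueError("baseline and frame dimensions differ")
        diff = lum - rgb2gray(baseline)

    marker = np.zeros(frame.shape[:2], dtype=bool)
    if marker_spec is not None:
        marker = match_colour(frame, marker_spec)

    candidates = calib.tile_mask & ~marker
    if threshold is None:
        vals = diff[candidates]
        if vals.size == 0:
            grazed = np.zeros_like(candidates)
        elif vals.max() - vals.min() < _MIN_CONTRAST:
            # no within-substrate contrast: uniformly grazed or uniformly intact
            grazed = candidates.copy() if vals.mean() > _MIN_CONTRAST else np.zeros_like(candidates)
        else:
            grazed = candidates & (diff > threshold_otsu(vals))
    else:
        grazed = candidates & (diff > threshold)

    if marker.any():
        # the substrate under a grazer cannot be observed: classify each
        # excluded pixel like its nearest visible neighbour
        iy, ix = distance_transform_edt(marker, return_distances=False, return_indices=True)
        filled = grazed[iy, ix]
        grazed = np.where(marker, filled & calib.tile_mask, grazed)
    if min_component_px > 1 and grazed.any():
        grazed = morphology.remove_small_objects(grazed, max_size=min_component_px - 1)
    return grazed


def polygon_mask(polygons, shape: tuple[int, int]) -> np.ndarray:
    """Boolean mask from manually selected polygons.

    ``polygons`` is an iterable of (n, 2) vertex arrays in (x_px, y_px)
    order — the format of a hand-digitised selection exported as CSV. Use
    with :func:`area_from_mask` to reproduce a manual grazed-area
    quantification instead of the automatic thresholding.
    """
    from skimage.draw import polygon as _draw_polygon

    mask = np.zeros(shape, dtype=bool)
    for verts in polygons:
        verts = np.asarray(verts, dtype=float)
        if verts.ndim != 2 or verts.shape[1] != 2 or len(verts) < 3:
            raise ValueError("each polygon needs at least 3 (x, y) vertices")
        rr, cc = _draw_polygon(verts[:, 1], verts[:, 0], shape=shape)
        mask[rr, cc] = True
    return mask


def polygons_from_table(table: pd.DataFrame) -> dict[int, list[np.ndarray]]:
    """Group a vertex CSV (frame, polygon_id, x_px, y_px) into per-frame
    vertex arrays accepted by :func:`polygon_mask`."""
    out: dict[int, list[np.ndarray]] = {}
    for (frame, _pid), grp in table.groupby(["frame", "polygon_id"], sort=True):
        out.setdefault(int(frame), []).append(grp[["x_px", "y_px"]].to_numpy(dtype=float))
    return out


@dataclass(frozen=True)
class GrazedAreaSample:
    time_h: float
    grazed_px: int
    grazed_cm2: float
    fraction_percent: float


def grazed_fraction(grazed_cm2: float, total_cm2: float) -> float:
    """Percent of the substrate area grazed."""
    if total_cm2 <= 0:
        raise ValueError("total_cm2 must be positive")
    if grazed_cm2 < 0:
        raise ValueError("grazed_cm2 must be >= 0")
    if grazed_cm2 > total_cm2 * (1 + 1e-9):
        warnings.warn(
            f"grazed area {grazed_cm2:.3g} exceeds substrate area {total_cm2:.3g}",
            stacklevel=2,
        )
    return 100.0 * grazed_cm2 / total_cm2


def area_from_mask(mask: np.ndarray, calib: Calibration, time_h: float = 0.0) -> GrazedAreaSample:
    """Calibrated area sample from a boolean grazed mask."""
    px = int(np.asarray(mask, dtype=bool).sum())
    cm2 = px / calib.px_per_cm**2
    return GrazedAreaSample(
        time_h=time_h,
        grazed_px=px,
        grazed_cm2=cm2,
        fraction_percent=grazed_fraction(cm2, calib.total_substrate_cm2),
    )


def area_series(
    frames: np.ndarray,
    times_h: np.ndarray,
    baseline: np.ndarray | float,
    calib: Calibration,
    threshold: float | None = None,
    marker_spec: ColourSpec | None = None,
    **segment_kwargs,
) -> list[GrazedAreaSample]:
    """Grazed-area sample per analysed frame (frames in temporal order)."""
    if len(frames) != len(times_h):
        raise ValueError("need one timestamp per frame")
    samples = []
    for frame, t in zip(frames, times_h):
        mask = segment_grazed(
            frame, baseline, calib, threshold=threshold, marker_spec=marker_spec, **segment_kwargs
        )
        samples.append(area_from_mask(mask, calib, time_h=float(t)))
    return samples


def series_to_table(samples: list[GrazedAreaSample], flume_id: str = "") -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "flume": flume_id,
                "time_h": s.time_h,
                "grazed_px": s.grazed_px,
                "grazed_cm2": s.grazed_cm2,
                "fraction_percent": s.fraction_percent,
            }
            for s in samples
        ],
        columns=["flume", "time_h", "grazed_px", "grazed_cm2", "fraction_percent"],
    )
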