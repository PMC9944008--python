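"""Synthetic flume scenes with known ground truth.

This module emulates the three kinds of raw data produced by a factorial
flume grazing experiment (two phosphorus levels x grazer presence/absence):

* grazer trajectories driven by a three-state (resting / slow / fast)
  Markov movement model, so that every downstream estimator (detection,
  linking, speed classification, grazed-area measurement) can be scored
  against latent truth;
* rendered top-view frame sequences in which each grazer carries a pink
  colour marker and depletes the biofilm along its path, exposing the bare
  white ceramic tile underneath;
* assay tables (elemental C/P, dry mass, pigment concentrations) drawn from
  configurable per-treatment distributions, with the generating algal-group
  compositions returned as ground truth.

Units: flume coordinates are centimetres (x along the flume, y across it),
time in seconds, speeds in cm per hour. Pixel coordinates follow image
convention: origin at the top-left pixel, x rightward (columns), y downward
(rows), with a pixel's coordinate equal to its 0-based index.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

STATE_NAMES: tuple[str, str, str] = ("resting", "slow", "fast")

# speed-category boundaries (cm/h) used by the downstream classifier
RESTING_MAX = 0.4
SLOW_MAX = 4.0


@dataclass(frozen=True)
class SceneConfig:
    """Geometry, optics and timing of one simulated flume.

    Defaults reproduce the physical set-up: a 62 x 8 cm flume holding a
    3 x 10 grid of 2.3 cm ceramic tiles (158.7 cm^2 of substrate), eight
    colour-marked grazers, one frame every 15 s.
    """

    flume_length_cm: float = 62.0
    flume_width_cm: float = 8.0
    tile_side_cm: float = 2.3
    tile_rows: int = 3
    tile_cols: int = 10
    removed_tiles: tuple[int, ...] = ()
    px_per_cm: float = 5.0
    frame_interval_s: float = 15.0
    duration_s: float = 7200.0
    n_grazers: int = 8
    marker_rgb: tuple[int, int, int] = (255, 82, 168)
    marker_radius_cm: float = 0.25
    mouth_radius_cm: float = 0.25
    biofilm_rgb: tuple[int, int, int] = (96, 108, 58)
    bare_rgb: tuple[int, int, int] = (228, 226, 218)
    floor_rgb: tuple[int, int, int] = (148, 148, 148)
    light_cycle_h: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.px_per_cm <= 0:
            raise ValueError("px_per_cm must be positive")
        if self.frame_interval_s <= 0:
            raise ValueError("frame_interval_s must be positive")
        if self.duration_s < 0:
            raise ValueError("duration_s must be non-negative")
        if self.n_grazers < 0:
            raise ValueError("n_grazers must be >= 0")
        if self.tile_cols * self.tile_side_cm > self.flume_length_cm + 1e-9:
            raise ValueError("tile grid does not fit along the flume")
        if self.tile_rows * self.tile_side_cm > self.flume_width_cm + 1e-9:
            raise ValueError("tile grid does not fit across the flume")
        n_tiles = self.tile_rows * self.tile_cols
        for idx in self.removed_tiles:
            if not 0 <= idx < n_tiles:
                raise ValueError(f"removed tile index {idx} outside grid")
        for other, name in ((self.biofilm_rgb, "biofilm_rgb"), (self.bare_rgb, "bare_rgb")):
            if tuple(self.marker_rgb) == tuple(other):
                raise ValueError(f"marker_rgb must differ from {name}")

    # -- derived geometry ----------------------------------------------------

    @property
    def n_frames(self) -> int:
        return int(round(self.duration_s / self.frame_interval_s)) + 1

    @property
    def frame_shape(self) -> tuple[int, int]:
        """(height, width) of rendered frames, pixels."""
        return (
            int(round(self.flume_width_cm * self.px_per_cm)),
            int(round(self.flume_length_cm * self.px_per_cm)),
        )

    @property
    def tray_origin_cm(self) -> tuple[float, float]:
        """(x, y) of the tile tray's top-left corner; the tray is centred."""
        x0 = (self.flume_length_cm - self.tile_cols * self.tile_side_cm) / 2.0
        y0 = (self.flume_width_cm - self.tile_rows * self.tile_side_cm) / 2.0
        return x0, y0

    def tile_mask(self) -> np.ndarray:
        """Boolean raster of substrate pixels (present tiles only).

        Tile indices run row-major: index = row * tile_cols + col, mirroring
        the 3 x 10 grid layout.
        """
        h, w = self.frame_shape
        yy, xx = np.mgrid[0:h, 0:w]
        x_cm = xx / self.px_per_cm
        y_cm = yy / self.px_per_cm
        x0, y0 = self.tray_origin_cm
        col = np.floor((x_cm - x0) / self.tile_side_cm).astype(int)
        row = np.floor((y_cm - y0) / self.tile_side_cm).astype(int)
        inside = (
            (x_cm >= x0)
            & (x_cm < x0 + self.tile_cols * self.tile_side_cm)
            & (y_cm >= y0)
            & (y_cm < y0 + self.tile_rows * self.tile_side_cm)
        )
        mask = inside.copy()
        if self.removed_tiles:
            idx = row * self.tile_cols + col
            removed = np.isin(idx, np.asarray(self.removed_tiles, dtype=int))
            mask &= ~removed
        return mask

    def frame_times_s(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_interval_s

    def lit_frames(self) -> np.ndarray:
        """Boolean per frame: True where the light phase is on.

        With ``light_cycle_h`` unset (default) every frame is lit; otherwise
        a light:dark cycle of that half-period alternates, starting lit.
        """
        if self.light_cycle_h is None:
            return np.ones(self.n_frames, dtype=bool)
        t_h = self.frame_times_s() / 3600.0
        return (t_h % (2 * self.light_cycle_h)) < self.light_cycle_h


def _default_transition() -> np.ndarray:
    return np.array(
        [
            [0.90, 0.08, 0.02],
            [0.15, 0.70, 0.15],
            [0.05, 0.25, 0.70],
        ]
    )


def _default_speed_ranges() -> dict[str, tuple[float, float]]:
    return {"resting": (0.0, 0.36), "slow": (0.5, 3.8), "fast": (4.4, 10.0)}


@dataclass(frozen=True)
class BehaviourModel:
    """State-switching correlated random walk for a slow benthic grazer.

    States switch per frame interval following ``transition_matrix``
    (row-stochastic, rows ordered resting/slow/fast). Within a state, the
    interval speed is drawn uniformly from ``speed_ranges[state]`` (cm/h);
    each support must lie strictly inside the corresponding classifier band
    (resting [0, 0.4), slow [0.4, 4], fast (4, inf)) so that latent states
    remain recoverable from noisy measurements. Headings evolve by von Mises
    turning-angle increments with concentration ``turning_kappa``.
    """

    transition_matrix: np.ndarray = field(default_factory=_default_transition)
    speed_ranges: Mapping[str, tuple[float, float]] = field(default_factory=_default_speed_ranges)
    turning_kappa: float = 4.0

    def __post_init__(self) -> None:
        tm = np.asarray(self.transition_matrix, dtype=float)
        object.__setattr__(self, "transition_matrix", tm)
        if tm.shape != (3, 3):
            raise ValueError("transition_matrix must be 3x3")
        if np.any(tm < 0) or np.any(np.abs(tm.sum(axis=1) - 1.0) > 1e-12):
            raise ValueError("transition_matrix rows must be non-negative and sum to 1")
        ranges = {s: tuple(map(float, self.speed_ranges[s])) for s in STATE_NAMES}
        object.__setattr__(self, "speed_ranges", ranges)
        lo, hi = ranges["resting"]
        if not (0.0 <= lo <= hi < RESTING_MAX):
            raise ValueError("resting speed support must lie inside [0, 0.4)")
        lo, hi = ranges["slow"]
        if not (RESTING_MAX < lo <= hi < SLOW_MAX):
            raise ValueError("slow speed support must lie strictly inside (0.4, 4)")
        lo, hi = ranges["fast"]
        if not (SLOW_MAX < lo <= hi):
            raise ValueError("fast speed support must lie strictly above 4")
        if self.turning_kappa < 0:
            raise ValueError("turning_kappa must be >= 0")

    @property
    def max_speed(self) -> float:
        return max(hi for _, hi in self.speed_ranges.values())

    def stationary_distribution(self) -> np.ndarray:
        """Stationary state distribution (left eigenvector for eigenvalue 1)."""
        w, v = np.linalg.eig(self.transition_matrix.T)
        i = int(np.argmin(np.abs(w - 1.0)))
        pi = np.real(v[:, i])
        pi = np.abs(pi)
        return pi / pi.sum()


def boundary_resolvable_behaviour() -> BehaviourModel:
    """Behaviour preset whose speed supports keep a wide margin from the
    classifier boundaries, for profiles where per-interval displacements at
    the boundaries span at least a pixel."""
    return BehaviourModel(
        speed_ranges={"resting": (0.0, 0.30), "slow": (0.6, 3.6), "fast": (4.6, 10.0)},
    )


@dataclass(frozen=True)
class GroundTruth:
    """Latent truth of one simulated flume.

    ``positions[t, g]`` is grazer ``g``'s (x, y) in cm at frame ``t``;
    ``states[t, g]`` is the state governing the interval t -> t+1 (the last
    row is the state drawn at the final frame, unused for movement);
    ``speeds[t, g]`` the generated speed of that interval (cm/h).
    """

    scene: SceneConfig
    positions: np.ndarray
    states: np.ndarray
    speeds: np.ndarray
    treatment: str = ""

    @property
    def n_frames(self) -> int:
        return self.positions.shape[0]

    @property
    def n_grazers(self) -> int:
        return self.positions.shape[1]

    def trajectory_table(self) -> pd.DataFrame:
        n_f, n_g = self.states.shape
        frames = np.repeat(np.arange(n_f), n_g)
        grazers = np.tile(np.arange(n_g), n_f)
        return pd.DataFrame(
            {
                "frame": frames,
                "grazer_id": grazers,
                "x_cm": self.positions[:, :, 0].ravel(),
                "y_cm": self.positions[:, :, 1].ravel(),
                "state": [STATE_NAMES[s] for s in self.states.ravel()],
            }
        )

    def interval_table(self) -> pd.DataFrame:
        """One row per grazer per frame interval with latent state and speed."""
        n_int = self.n_frames - 1
        n_g = self.n_grazers
        frames = np.repeat(np.arange(n_int), n_g)
        grazers = np.tile(np.arange(n_g), n_int)
        return pd.DataFrame(
            {
                "frame_from": frames,
                "frame_to": frames + 1,
                "grazer_id": grazers,
                "speed_cm_per_h": self.speeds.ravel() if n_int else np.empty(0),
                "state": [STATE_NAMES[s] for s in self.states[:-1].ravel()],
            }
        )

    def positions_px(self) -> np.ndarray:
        return self.positions * self.scene.px_per_cm


def simulate_trajectories(
    scene: SceneConfig,
    behaviour: BehaviourModel | None = None,
    seed: int | None = None,
    initial_states: Sequence[int] | str | None = None,
) -> GroundTruth:
    """Simulate grazer trajectories with latent behavioural states.

    Each interval: draw the state from the Markov chain, a speed uniform in
    the state's support and a heading update; step in a straight line so the
    net displacement equals speed x interval exactly. At a wall the heading
    component pointing out of the flume is flipped (specular reflection of
    the direction) before the step, which keeps both the displacement
    magnitude and the flume bounds. Deterministic given the seed.
    """
    behaviour = behaviour if behaviour is not None else BehaviourModel()
    if seed is None:
        seed = scene.seed
    rng = np.random.default_rng(seed)

    dt_h = scene.frame_interval_s / 3600.0
    margin = min(scene.marker_radius_cm, scene.flume_width_cm / 4)
    lo_x, hi_x = margin, scene.flume_length_cm - margin
    lo_y, hi_y = margin, scene.flume_width_cm - margin
    max_step = behaviour.max_speed * dt_h
    if max_step >= min(hi_x - lo_x, hi_y - lo_y) / 2:
        raise ValueError(
            "per-interval step exceeds half the free flume extent; "
            "reduce max speed or frame interval"
        )

    n_g = scene.n_grazers
    n_f = scene.n_frames
    lo = np.array([behaviour.speed_ranges[s][0] for s in STATE_NAMES])
    hi = np.array([behaviour.speed_ranges[s][1] for s in STATE_NAMES])
    cdf = np.cumsum(behaviour.transition_matrix, axis=1)

    positions = np.empty((n_f, n_g, 2))
    states = np.empty((n_f, n_g), dtype=np.int64)
    speeds = np.empty((max(n_f - 1, 0), n_g))

    positions[0, :, 0] = rng.uniform(lo_x, hi_x, n_g)
    positions[0, :, 1] = rng.uniform(lo_y, hi_y, n_g)
    if initial_states is None:
        pi = behaviour.stationary_distribution()
        states[0] = rng.choice(3, size=n_g, p=pi)
    elif isinstance(initial_states, str):
        states[0] = STATE_NAMES.index(initial_states)
    else:
        states[0] = np.asarray(initial_states, dtype=np.int64)
    heading = rng.uniform(-np.pi, np.pi, n_g)

    for t in range(n_f - 1):
        s = states[t]
        v = rng.uniform(lo[s], hi[s])
        if behaviour.turning_kappa > 0:
            heading = heading + rng.vonmises(0.0, behaviour.turning_kappa, n_g)
        else:
            heading = rng.uniform(-np.pi, np.pi, n_g)
        step = v * dt_h
        dx = step * np.cos(heading)
        dy = step * np.sin(heading)
        x, y = positions[t, :, 0], positions[t, :, 1]
        flip_x = ((x + dx) < lo_x) | ((x + dx) > hi_x)
        flip_y = ((y + dy) < lo_y) | ((y + dy) > hi_y)
        dx = np.where(flip_x, -dx, dx)
        dy = np.where(flip_y, -dy, dy)
        positions[t + 1, :, 0] = x + dx
        positions[t + 1, :, 1] = y + dy
        moved = step > 0
        heading = np.where(moved, np.arctan2(dy, dx), heading)
        speeds[t] = v
        u = rng.random(n_g)
        states[t + 1] = (u[:, None] <= cdf[s]).argmax(axis=1)

    return GroundTruth(scene=scene, positions=positions, states=states, speeds=speeds)


def simulate_noncrossing(
    scene: SceneConfig,
    behaviour: BehaviourModel | None = None,
    seed: int = 0,
    min_separation_cm: float | None = None,
    max_tries: int = 200,
) -> GroundTruth:
    """Simulate until all grazers stay mutually separated in every frame.

    Identity linking by nearest neighbour is only well-posed when paths do
    not cross; this helper redraws the simulation (with seeds derived from
    ``seed``) until the minimum pairwise distance over all frames exceeds
    ``min_separation_cm`` (default: twice the marker diameter plus twice the
    largest per-interval step).
    """
    behaviour = behaviour if behaviour is not None else BehaviourModel()
    if min_separation_cm is None:
        step = behaviour.max_speed * scene.frame_interval_s / 3600.0
        min_separation_cm = 4 * scene.marker_radius_cm + 2 * step
    for k in range(max_tries):
        truth = simulate_trajectories(scene, behaviour, seed=(seed + 10007 * k) % (2**31))
        if truth.n_grazers < 2:
            return truth
        if _min_pairwise_distance(truth.positions) > min_separation_cm:
            return truth
    raise RuntimeError(
        f"no non-crossing realisation found in {max_tries} tries; "
        "reduce n_grazers, duration or speeds"
    )


def _min_pairwise_distance(positions: np.ndarray) -> float:
    n_g = positions.shape[1]
    best = np.inf
    for i in range(n_g):
        for j in range(i + 1, n_g):
            d = np.hypot(
                positions[:, i, 0] - positions[:, j, 0],
                positions[:, i, 1] - positions[:, j, 1],
            ).min()
            best = min(best, d)
    return float(best)


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------


def _disc_window(shape: tuple[int, int], cx: float, cy: float, r: float):
    """Local window around a disc centre: slices plus the distance raster
    from each pixel coordinate (= index) to (cx, cy)."""
    h, w = shape
    x0 = max(int(np.floor(cx - r - 1)), 0)
    x1 = min(int(np.ceil(cx + r + 1)) + 1, w)
    y0 = max(int(np.floor(cy - r - 1)), 0)
    y1 = min(int(np.ceil(cy + r + 1)) + 1, h)
    if x0 >= x1 or y0 >= y1:
        return None
    yy, xx = np.mgrid[y0:y1, x0:x1]
    dist = np.hypot(xx - cx, yy - cy)
    return (slice(y0, y1), slice(x0, x1)), dist


def render_background(scene: SceneConfig) -> np.ndarray:
    """Intact-biofilm reference image (tray floor + tiled substrate)."""
    h, w = scene.frame_shape
    img = np.empty((h, w, 3), dtype=np.uint8)
    img[:] = np.asarray(scene.floor_rgb, dtype=np.uint8)
    img[scene.tile_mask()] = np.asarray(scene.biofilm_rgb, dtype=np.uint8)
    return img


def render_frames(
    truth: GroundTruth,
    scene: SceneConfig | None = None,
    draw_markers: bool = True,
    colour_tolerance: float = 60.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Render the frame sequence and the cumulative grazed mask per frame.

    Returns ``(frames, masks)``: frames as uint8 RGB of shape
    (n_frames, H, W, 3), masks boolean (n_frames, H, W). Biofilm pixels
    within ``mouth_radius_cm`` of any position visited up to frame t are
    grazed in mask t; grazing is restricted to (non-removed) tile pixels and
    is monotone over time. Markers are drawn as anti-aliased discs of
    ``marker_rgb``; the returned mask is the rendered grazed region itself.
    """
    if scene is None:
        scene = truth.scene
    for c, name in ((scene.biofilm_rgb, "biofilm_rgb"), (scene.bare_rgb, "bare_rgb")):
        d = float(np.linalg.norm(np.asarray(scene.marker_rgb, float) - np.asarray(c, float)))
        if d < colour_tolerance:
            warnings.warn(
                f"marker colour within detection tolerance of {name} "
                f"(RGB distance {d:.1f} < {colour_tolerance}); detection will be unreliable",
                stacklevel=2,
            )
    h, w = scene.frame_shape
    n_f = truth.n_frames
    bg = render_background(scene)
    tile_mask = scene.tile_mask()
    marker = np.asarray(scene.marker_rgb, dtype=float)
    bare = np.asarray(scene.bare_rgb, dtype=np.uint8)

    pos_px = truth.positions_px()
    mouth_r = scene.mouth_radius_cm * scene.px_per_cm
    marker_r = scene.marker_radius_cm * scene.px_per_cm

    frames = np.empty((n_f, h, w, 3), dtype=np.uint8)
    masks = np.empty((n_f, h, w), dtype=bool)
    grazed = np.zeros((h, w), dtype=bool)
    lit = scene.lit_frames()

    for t in range(n_f):
        for g in range(truth.n_grazers):
            win = _disc_window((h, w), pos_px[t, g, 0], pos_px[t, g, 1], mouth_r)
            if win is not None:
                sl, dist = win
                grazed[sl] |= dist <= mouth_r
        mask_t = grazed & tile_mask
        masks[t] = mask_t
        frame = bg.copy()
        frame[mask_t] = bare
        if draw_markers:
            for g in range(truth.n_grazers):
                win = _disc_window((h, w), pos_px[t, g, 0], pos_px[t, g, 1], marker_r)
                if win is None:
                    continue
                sl, dist = win
                alpha = np.clip(marker_r + 0.5 - dist, 0.0, 1.0)
                under = frame[sl].astype(float)
                frame[sl] = np.rint(
                    alpha[..., None] * marker + (1.0 - alpha[..., None]) * under
                ).astype(np.uint8)
        if not lit[t]:
            frame = (frame.astype(float) * 0.15).astype(np.uint8)
        frames[t] = frame
    return frames, masks


# ---------------------------------------------------------------------------
# assay tables
# ---------------------------------------------------------------------------

ATOMIC_MASS_C = 12.011
ATOMIC_MASS_P = 30.974


def default_pigment_library() -> pd.DataFrame:
    """Illustrative marker-pigment:chl-a ratio matrix for a two-group
    (diatoms / chlorophytes) periphyton community.

    Carries the full accessory-pigment signature each group would show on an
    HPLC run (fucoxanthin/chl-c/diadinoxanthin/diatoxanthin for diatoms;
    chl-b/lutein/zeaxanthin/violaxanthin/neoxanthin for chlorophytes): a
    rich marker set is what makes group abundances well-conditioned under
    measurement noise. Values are plausible field-style ratios, editable by
    the user; they are not measurements.
    """
    pigments = [
        "chlorophyll_a",
        "fucoxanthin",
        "chlorophyll_c2",
        "diadinoxanthin",
        "diatoxanthin",
        "chlorophyll_b",
        "lutein",
        "zeaxanthin",
        "violaxanthin",
        "neoxanthin",
    ]
    data = {
        "diatoms": [1.0, 0.80, 0.25, 0.40, 0.12, 0.0, 0.0, 0.0, 0.0, 0.0],
        "chlorophytes": [1.0, 0.0, 0.0, 0.0, 0.0, 0.50, 0.30, 0.10, 0.15, 0.08],
    }
    return pd.DataFrame.from_dict(data, orient="index", columns=pigments)


@dataclass(frozen=True)
class TreatmentAssay:
    """Per-treatment generating distributions for the assay tables."""

    label: str
    cp_mean: float
    cp_sd: float
    dry_mass_mean: float
    dry_mass_sd: float
    diatom_pct_mean: float
    diatom_pct_sd: float
    n: int

    def __post_init__(self) -> None:
        if min(self.cp_sd, self.dry_mass_sd, self.diatom_pct_sd) < 0:
            raise ValueError("standard deviations must be >= 0")
        if self.n < 2:
            raise ValueError("need n >= 2 replicates")


@dataclass(frozen=True)
class AssayConfig:
    """Generating configuration for elemental + pigment assay tables."""

    treatments: tuple[TreatmentAssay, ...]
    ratio_matrix: pd.DataFrame = field(default_factory=default_pigment_library)
    noise_cv: float = 0.05
    chla_per_dry_mass: float = 2.0  # ug chl a per mg dry mass
    c_fraction_dry: float = 0.30  # mass fraction of dry mass that is carbon

    def __post_init__(self) -> None:
        if not self.treatments:
            raise ValueError("at least one treatment required")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        F = self.ratio_matrix
        if "chlorophyll_a" not in F.columns:
            raise ValueError("ratio matrix must have a chlorophyll_a column")
        if (F.values < 0).any():
            raise ValueError("ratio matrix must be non-negative")
        if not np.allclose(F["chlorophyll_a"].values, 1.0):
            raise ValueError("chlorophyll_a column must be identically 1")


def start_phase_assay(**overrides) -> AssayConfig:
    """Defaults matching the pre-grazing phase of the experiment: six
    replicate flumes per phosphorus level, with molar C:P 144 +/- 26 (P+)
    vs 316 +/- 68 (P-), dry mass 1.91 +/- 0.15 vs 0.72 +/- 0.29 mg cm^-2 and
    diatom shares of 49 +/- 18 % vs 94 +/- 2 % of total chl a."""
    treatments = (
        TreatmentAssay("P+", 144.0, 26.0, 1.91, 0.15, 49.0, 18.0, 6),
        TreatmentAssay("P-", 316.0, 68.0, 0.72, 0.29, 94.0, 2.0, 6),
    )
    return AssayConfig(treatments=treatments, **overrides)


def end_phase_assay(**overrides) -> AssayConfig:
    """Defaults matching the post-grazing 2x2 design (three replicates per
    cell). Dry mass responds to both phosphorus and grazing; C:P and diatom
    share respond to phosphorus only."""
    treatments = (
        TreatmentAssay("P+G-", 144.0, 26.0, 3.18, 0.38, 49.0, 18.0, 3),
        TreatmentAssay("P+G+", 144.0, 26.0, 2.48, 0.13, 49.0, 18.0, 3),
        TreatmentAssay("P-G-", 316.0, 68.0, 1.33, 0.11, 94.0, 2.0, 3),
        TreatmentAssay("P-G+", 316.0, 68.0, 0.23, 0.06, 94.0, 2.0, 3),
    )
    return AssayConfig(treatments=treatments, **overrides)


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float) -> float:
    """Normal draw truncated at zero by redraw (values must be positive)."""
    if sd == 0:
        return float(mean)
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if x > 0:
            return float(x)
    raise RuntimeError("truncated normal rejection failed; check mean/sd")


def generate_assay_tables(
    assay: AssayConfig, seed: int = 0
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Draw elemental and pigment tables plus ground-truth compositions.

    Elemental rows carry per-replicate dry mass (mg cm^-2) and C/P masses
    (ug cm^-2) constructed so that the molar C:P of the row equals the drawn
    ratio exactly. Pigment rows are group-abundance vectors (chl-a units)
    times the ratio matrix, each entry multiplied by independent lognormal
    noise of scale ``noise_cv`` (noiseless when 0). Returns
    ``(elemental, pigments, truth)`` DataFrames indexed by sample id.
    """
    rng = np.random.default_rng(seed)
    F = assay.ratio_matrix
    groups = list(F.index)
    elemental_rows = []
    pigment_rows = []
    truth_rows = []
    for tr in assay.treatments:
        for i in range(tr.n):
            sample = f"{tr.label}-{i + 1}"
            cp = _truncated_normal(rng, tr.cp_mean, tr.cp_sd)
            dm = _truncated_normal(rng, tr.dry_mass_mean, tr.dry_mass_sd)
            c_ug = dm * 1000.0 * assay.c_fraction_dry
            p_ug = (c_ug / ATOMIC_MASS_C) * ATOMIC_MASS_P / cp
            diatom_pct = float(np.clip(rng.normal(tr.diatom_pct_mean, tr.diatom_pct_sd), 0.0, 100.0))
            elemental_rows.append(
                {
                    "sample": sample,
                    "treatment": tr.label,
                    "dry_mass_mg_per_cm2": dm,
                    "C_ug_per_cm2": c_ug,
                    "P_ug_per_cm2": p_ug,
                    "molar_cp": cp,
                }
            )
            chla = dm * assay.chla_per_dry_mass
            shares = np.empty(len(groups))
            if "diatoms" in groups:
                di = groups.index("diatoms")
                shares[:] = (100.0 - diatom_pct) / max(len(groups) - 1, 1) / 100.0
                shares[di] = diatom_pct / 100.0
            else:
                shares[:] = 1.0 / len(groups)
            abund = chla * shares
            conc = abund @ F.values
            if assay.noise_cv > 0:
                conc = conc * np.exp(rng.normal(0.0, assay.noise_cv, size=conc.shape))
            pigment_rows.append({"sample": sample, **dict(zip(F.columns, conc))})
            truth_rows.append(
                {
                    "sample": sample,
                    "treatment": tr.label,
                    **{f"abundance_{g}": a for g, a in zip(groups, abund)},
                    **{f"percent_{g}": 100.0 * s for g, s in zip(groups, shares)},
                }
            )
    elemental = pd.DataFrame(elemental_rows).set_index("sample")
    pigments = pd.DataFrame(pigment_rows).set_index("sample")
    truth = pd.DataFrame(truth_rows).set_index("sample")
    return elemental, pigments, truth
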