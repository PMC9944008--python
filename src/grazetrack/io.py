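"""Plain-text / PNG interchange for pipeline stages.

Every stage writes and reads simple formats (numbered PNG frames, CSV
tables, YAML configs) so that any stage can be re-run standalone, or fed
real footage instead of synthetic frames.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import yaml

from .scene import BehaviourModel, SceneConfig


def write_frames_png(frames: np.ndarray, outdir: str | Path, prefix: str = "frame") -> list[Path]:
    """Write a (n, H, W, 3) uint8 stack as zero-padded numbered PNGs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    width = max(4, len(str(len(frames) - 1)))
    paths = []
    for i, frame in enumerate(frames):
        p = outdir / f"{prefix}_{i:0{width}d}.png"
        iio.imwrite(p, frame)
        paths.append(p)
    return paths


def read_frames_dir(directory: str | Path, pattern: str = "*.png") -> np.ndarray:
    """Read a directory of equally sized frames, sorted by filename."""
    paths = sorted(Path(directory).glob(pattern))
    if not paths:
        raise FileNotFoundError(f"no frames matching {pattern} in {directory}")
    return np.stack([iio.imread(p) for p in paths])


def write_mask_png(mask: np.ndarray, path: str | Path) -> None:
    iio.imwrite(Path(path), (np.asarray(mask, dtype=np.uint8) * 255))


def scene_to_dict(scene: SceneConfig) -> dict:
    d = dataclasses.asdict(scene)
    d["removed_tiles"] = list(d["removed_tiles"])
    for key in ("marker_rgb", "biofilm_rgb", "bare_rgb", "floor_rgb"):
        d[key] = list(d[key])
    return d


def scene_from_dict(d: dict) -> SceneConfig:
    d = dict(d)
    d["removed_tiles"] = tuple(d.get("removed_tiles", ()))
    for key in ("marker_rgb", "biofilm_rgb", "bare_rgb", "floor_rgb"):
        if key in d:
            d[key] = tuple(d[key])
    return SceneConfig(**d)


def behaviour_to_dict(behaviour: BehaviourModel) -> dict:
    return {
        "transition_matrix": np.asarray(behaviour.transition_matrix).tolist(),
        "speed_ranges": {k: list(v) for k, v in behaviour.speed_ranges.items()},
        "turning_kappa": behaviour.turning_kappa,
    }


def behaviour_from_dict(d: dict) -> BehaviourModel:
    return BehaviourModel(
        transition_matrix=np.asarray(d["transition_matrix"], dtype=float),
        speed_ranges={k: tuple(v) for k, v in d["speed_ranges"].items()},
        turning_kappa=float(d.get("turning_kappa", 4.0)),
    )


def write_yaml(obj: dict, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        yaml.safe_dump(obj, fh, sort_keys=True)


def read_yaml(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)
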