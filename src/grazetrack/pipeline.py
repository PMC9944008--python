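"""End-to-end orchestration: simulate -> detect -> track -> classify ->
area -> unmix -> stats, from one configuration and one global seed.

Each stage's output is a plain CSV under the run directory, so single
stages can be re-run or replaced with real data. Flume-level seeds are
derived from the global seed by fixed offsets, making a run bitwise
reproducible. Grazer-free (G-) flumes skip tracking and kinematics; their
grazed area is still measured (and is zero by construction) and they enter
the assay and statistics stages like any other flume.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as gio
from .area import Calibration, area_series, series_to_table, tile_total_area
from .chemtax import composition_percent, optimize_ratios, perturb_ratio_matrix
from .detect import ColourSpec, default_blob_limits, detect_sequence, detections_to_table
from .kinematics import compute_speeds, counts_to_table, records_to_table, tally_categories
from .linking import LinkParams, link_sequence, suggested_max_step_px, tracks_to_table
from .scene import (
    BehaviourModel,
    SceneConfig,
    end_phase_assay,
    generate_assay_tables,
    render_background,
    render_frames,
    simulate_trajectories,
    start_phase_assay,
)
from .stats import GroupSummary, compare_two_groups, factorial_anova, grazing_rate

log = logging.getLogger("grazetrack.pipeline")

TREATMENTS = ("P+G+", "P+G-", "P-G+", "P-G-")


def behaviour_for_treatment(treatment: str) -> BehaviourModel:
    """Default movement regimes: P+ grazers rest more, P- grazers move fast
    more often (richer food shortens foraging excursions)."""
    if treatment.startswith("P+"):
        tm = [[0.95, 0.04, 0.01], [0.30, 0.60, 0.10], [0.20, 0.30, 0.50]]
    else:
        tm = [[0.80, 0.10, 0.10], [0.10, 0.60, 0.30], [0.04, 0.16, 0.80]]
    return BehaviourModel(transition_matrix=np.asarray(tm, dtype=float))


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one end-to-end run.

    ``replicates`` is the number of flumes per treatment that get the video
    pipeline; assay tables follow their own per-treatment replicate counts.
    The desk profile (default scene) simulates 2 h at 15 s frames; the full
    experiment-scale profile stretches duration to 14 days and the
    area-sampling interval to 12 h.
    """

    scene: SceneConfig = field(default_factory=SceneConfig)
    replicates: int = 1
    seed: int = 0
    colour_tolerance: float = 60.0
    max_gap_frames: int = 20
    area_every_n_frames: int = 40
    write_frames: bool = False
    grazing_duration_h: float | None = None  # default: scene duration

    def flume_specs(self) -> list[tuple[str, str]]:
        """(flume_id, treatment) pairs, video flumes."""
        return [
            (f"{tr}-{r + 1}", tr)
            for tr in TREATMENTS
            for r in range(self.replicates)
        ]


def desk_config(seed: int = 0, replicates: int = 1, **overrides) -> RunConfig:
    return RunConfig(scene=SceneConfig(), replicates=replicates, seed=seed, **overrides)


def full_scale_config(seed: int = 0, replicates: int = 3, **overrides) -> RunConfig:
    scene = SceneConfig(duration_s=14 * 24 * 3600.0)
    overrides.setdefault("area_every_n_frames", int(12 * 3600 / scene.frame_interval_s))
    return RunConfig(scene=scene, replicates=replicates, seed=seed, **overrides)


def _flume_seed(seed: int, index: int) -> int:
    return (seed + 1009 * (index + 1)) % (2**31)


def _write_csv(df: pd.DataFrame, path: Path, manifest_files: list, index: bool = False) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=index)
    manifest_files.append(str(path))


def run_flume_video(
    flume_id: str,
    treatment: str,
    config: RunConfig,
    seed: int,
    outdir: Path,
    files: list,
) -> dict:
    """Video pipeline for one flume; returns its summary block."""
    scene = dataclasses.replace(
        config.scene, n_grazers=config.scene.n_grazers if treatment.endswith("G+") else 0
    )
    behaviour = behaviour_for_treatment(treatment)
    t0 = time.perf_counter()
    truth = simulate_trajectories(scene, behaviour, seed=seed)
    frames, masks = render_frames(truth, scene)
    log.info("%s: simulated+rendered %d frames in %.2fs", flume_id, len(frames), time.perf_counter() - t0)

    fdir = outdir / "flumes" / flume_id
    _write_csv(truth.trajectory_table(), fdir / "ground_truth.csv", files)
    if config.write_frames:
        files.extend(map(str, gio.write_frames_png(frames, fdir / "frames")))

    summary: dict = {"treatment": treatment, "n_grazers": scene.n_grazers}

    marker_r_px = scene.marker_radius_cm * scene.px_per_cm
    if scene.n_grazers > 0:
        spec = ColourSpec(scene.marker_rgb, tolerance=config.colour_tolerance)
        min_px, max_px = default_blob_limits(marker_r_px)
        dets = detect_sequence(frames, spec, min_px, max_px)
        _write_csv(detections_to_table(dets), fdir / "detections.csv", files)
        params = LinkParams(
            n_expected=scene.n_grazers,
            max_step_px=suggested_max_step_px(
                behaviour.max_speed, scene.frame_interval_s, scene.px_per_cm
            ),
            max_gap_frames=config.max_gap_frames,
        )
        tracks = link_sequence(dets, params)
        _write_csv(tracks_to_table(tracks), fdir / "tracks.csv", files)
        records = []
        for tr in tracks:
            records.extend(
                compute_speeds(tr, scene.px_per_cm, scene.frame_interval_s, flume_id=flume_id)
            )
    else:
        records = []
        _write_csv(detections_to_table([]), fdir / "detections.csv", files)
        _write_csv(tracks_to_table([]), fdir / "tracks.csv", files)
    _write_csv(records_to_table(records), fdir / "movements.csv", files)
    counts = tally_categories(records, treatments={flume_id: treatment})
    _write_csv(counts_to_table(counts), fdir / "category_counts.csv", files)
    if counts:
        c = counts[0]
        summary["category_counts"] = {"resting": c.resting, "slow": c.slow, "fast": c.fast}
    else:
        summary["category_counts"] = {"resting": 0, "slow": 0, "fast": 0}

    calib = Calibration.from_scene(scene)
    baseline = render_background(scene)
    idx = list(range(0, len(frames), config.area_every_n_frames))
    if idx[-1] != len(frames) - 1:
        idx.append(len(frames) - 1)
    times_h = scene.frame_times_s()[idx] / 3600.0
    spec = ColourSpec(scene.marker_rgb, tolerance=config.colour_tolerance)
    samples = area_series(frames[idx], times_h, baseline, calib, marker_spec=spec)
    _write_csv(series_to_table(samples, flume_id), fdir / "area.csv", files)
    final = samples[-1]
    summary["grazed_final_cm2"] = final.grazed_cm2
    summary["grazed_final_percent"] = final.fraction_percent
    summary["grazed_truth_cm2"] = float(masks[-1].sum()) / scene.px_per_cm**2
    return summary


def run_pipeline(config: RunConfig, outdir: str | Path) -> dict:
    """Execute all stages; returns (and writes) the run manifest.

    The manifest lists every output file, per-stage parameters and per-flume
    errors (a failing flume is recorded and does not abort the others).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    files: list[str] = []
    errors: dict[str, str] = {}
    summary: dict = {"flumes": {}, "assay": {}, "stats": {}}

    gio.write_yaml(
        {
            "scene": gio.scene_to_dict(config.scene),
            "replicates": config.replicates,
            "seed": config.seed,
            "colour_tolerance": config.colour_tolerance,
            "area_every_n_frames": config.area_every_n_frames,
        },
        outdir / "config.yaml",
    )
    files.append(str(outdir / "config.yaml"))

    for i, (flume_id, treatment) in enumerate(config.flume_specs()):
        try:
            summary["flumes"][flume_id] = run_flume_video(
                flume_id, treatment, config, _flume_seed(config.seed, i), outdir, files
            )
        except Exception as exc:  # noqa: BLE001 - record and continue
            log.exception("flume %s failed", flume_id)
            errors[flume_id] = f"{type(exc).__name__}: {exc}"

    # ---- assay tables ------------------------------------------------------
    start_cfg = start_phase_assay()
    end_cfg = end_phase_assay()
    elem_start, pig_start, truth_start = generate_assay_tables(start_cfg, seed=_flume_seed(config.seed, 101))
    elem_end, pig_end, truth_end = generate_assay_tables(end_cfg, seed=_flume_seed(config.seed, 102))
    adir = outdir / "assay"
    _write_csv(elem_start, adir / "elemental_start.csv", files, index=True)
    _write_csv(pig_start, adir / "pigments_start.csv", files, index=True)
    _write_csv(truth_start, adir / "composition_truth_start.csv", files, index=True)
    _write_csv(elem_end, adir / "elemental_end.csv", files, index=True)
    _write_csv(pig_end, adir / "pigments_end.csv", files, index=True)
    _write_csv(truth_end, adir / "composition_truth_end.csv", files, index=True)

    # ---- pigment unmixing (one ratio matrix per P level) -------------------
    comp_rows = []
    for p_level in ("P+", "P-"):
        sel = pig_start.index.str.startswith(p_level)
        S = pig_start.loc[sel]
        F0 = perturb_ratio_matrix(
            start_cfg.ratio_matrix, 0.2, seed=_flume_seed(config.seed, 201 if p_level == "P+" else 202)
        )
        fit = optimize_ratios(S, F0, seed=_flume_seed(config.seed, 203))
        comp = composition_percent(fit.abundances)
        comp_rows.append(comp)
        tag = "p_plus" if p_level == "P+" else "p_minus"
        _write_csv(fit.ratio_matrix, adir / f"ratio_matrix_final_{tag}.csv", files, index=True)
        _write_csv(
            pd.DataFrame({"iteration": range(1, len(fit.rms_log) + 1), "rms": fit.rms_log}),
            adir / f"unmixing_rms_log_{tag}.csv",
            files,
        )
        summary["assay"][f"diatom_percent_mean_{tag}"] = float(comp["diatoms"].mean())
        summary["assay"][f"unmixing_rms_{tag}"] = fit.rms
        summary["assay"][f"unmixing_converged_{tag}"] = bool(fit.converged)
    composition = pd.concat(comp_rows)
    _write_csv(composition, adir / "composition.csv", files, index=True)

    # ---- statistics --------------------------------------------------------
    sdir = outdir / "stats"
    test_rows = []

    def add_test(label: str, result) -> None:
        test_rows.append(
            {
                "comparison": label,
                "test": result.name,
                "statistic": result.statistic,
                "df": result.df,
                "p_value": result.p_value,
                "note": result.note,
            }
        )
        summary["stats"][label] = {
            "test": result.name,
            "statistic": result.statistic,
            "df": result.df,
            "p": result.p_value,
        }

    g = elem_start.groupby("treatment")
    add_test(
        "cp_start_p_plus_vs_p_minus",
        compare_two_groups(
            g.get_group("P+")["molar_cp"].values, g.get_group("P-")["molar_cp"].values, "student"
        ),
    )
    add_test(
        "dry_mass_start_p_plus_vs_p_minus",
        compare_two_groups(
            g.get_group("P+")["dry_mass_mg_per_cm2"].values,
            g.get_group("P-")["dry_mass_mg_per_cm2"].values,
            "student",
        ),
    )
    di = composition.join(truth_start["treatment"])
    add_test(
        "diatom_pct_start_p_plus_vs_p_minus",
        compare_two_groups(
            di.loc[di["treatment"] == "P+", "diatoms"].values,
            di.loc[di["treatment"] == "P-", "diatoms"].values,
            "welch",
        ),
    )

    end = elem_end.copy()
    end["phosphorus"] = [t[:2] for t in end["treatment"]]
    end["grazing"] = [t[2:] for t in end["treatment"]]
    anova, tukey = factorial_anova(end, "dry_mass_mg_per_cm2", "phosphorus", "grazing")
    _write_csv(anova.to_frame(), sdir / "anova_dry_mass_end.csv", files)
    _write_csv(tukey, sdir / "tukey_dry_mass_end.csv", files)
    summary["stats"]["anova_dry_mass_end"] = {
        k: {"F": e.F, "p": e.p_value} for k, e in anova.factors.items()
    }

    # movement-category comparisons across replicate flumes (need >= 2)
    counts_df = pd.DataFrame(
        [
            {"flume": fid, "treatment": block["treatment"], **block["category_counts"]}
            for fid, block in summary["flumes"].items()
            if block["n_grazers"] > 0
        ]
    )
    if not counts_df.empty:
        _write_csv(counts_df, sdir / "category_counts.csv", files)
        by_tr = counts_df.groupby("treatment")
        if {"P+G+", "P-G+"} <= set(by_tr.groups) and config.replicates >= 2:
            add_test(
                "resting_detections_p_plus_vs_p_minus",
                compare_two_groups(
                    by_tr.get_group("P+G+")["resting"].values,
                    by_tr.get_group("P-G+")["resting"].values,
                    "student",
                ),
            )
            add_test(
                "fast_detections_p_plus_vs_p_minus",
                compare_two_groups(
                    by_tr.get_group("P+G+")["fast"].values,
                    by_tr.get_group("P-G+")["fast"].values,
                    "wilcoxon",
                ),
            )

    duration_h = (
        config.grazing_duration_h
        if config.grazing_duration_h is not None
        else config.scene.duration_s / 3600.0
    )
    substrate = tile_total_area(
        config.scene.tile_rows * config.scene.tile_cols - len(config.scene.removed_tiles),
        config.scene.tile_side_cm,
    )
    em = elem_end.groupby("treatment")["dry_mass_mg_per_cm2"].mean()
    for p_level, tag in (("P+", "p_plus"), ("P-", "p_minus")):
        rate = grazing_rate(
            em[f"{p_level}G-"], em[f"{p_level}G+"], substrate, config.scene.n_grazers, duration_h
        )
        summary["stats"][f"grazing_rate_ug_h_ind_{tag}"] = rate
    _write_csv(pd.DataFrame(test_rows), sdir / "tests.csv", files)

    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    files.append(str(outdir / "summary.json"))

    manifest = {
        "outdir": str(outdir),
        "seed": config.seed,
        "parameters": {
            "scene": gio.scene_to_dict(config.scene),
            "replicates": config.replicates,
            "colour_tolerance": config.colour_tolerance,
            "area_every_n_frames": config.area_every_n_frames,
            "grazing_duration_h": duration_h,
            "substrate_cm2": substrate,
        },
        "files": sorted(files),
        "errors": errors,
        "summary": summary,
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
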