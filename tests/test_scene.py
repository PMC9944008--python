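"""Synthetic scene generator: trajectories, rendering, assay tables."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from grazetrack.scene import (
    STATE_NAMES,
    AssayConfig,
    BehaviourModel,
    SceneConfig,
    TreatmentAssay,
    default_pigment_library,
    generate_assay_tables,
    render_background,
    render_frames,
    simulate_trajectories,
    start_phase_assay,
)

from conftest import stationary_from_matrix


def rest_only_behaviour() -> BehaviourModel:
    return BehaviourModel(
        transition_matrix=np.eye(3),
        speed_ranges={"resting": (0.0, 0.0), "slow": (0.5, 3.8), "fast": (4.4, 10.0)},
    )


class TestSimulateTrajectories:
    def test_absorbing_rest_state_freezes_positions(self):
        scene = SceneConfig(duration_s=300.0, n_grazers=5)
        truth = simulate_trajectories(scene, rest_only_behaviour(), seed=3, initial_states="resting")
        assert (truth.states == 0).all()
        assert np.array_equal(truth.positions, np.broadcast_to(truth.positions[0], truth.positions.shape))

    def test_zero_duration_gives_single_frame_and_no_intervals(self):
        scene = SceneConfig(duration_s=0.0, n_grazers=2)
        truth = simulate_trajectories(scene, seed=0)
        assert truth.positions.shape == (1, 2, 2)
        assert len(truth.interval_table()) == 0

    def test_state_frequencies_match_stationary_distribution(self):
        # iid rows: every state transitions with the stationary probabilities
        pi_target = np.array([0.5, 0.3, 0.2])
        tm = np.tile(pi_target, (3, 1))
        behaviour = BehaviourModel(transition_matrix=tm)
        pi = stationary_from_matrix(tm)
        assert np.allclose(pi, pi_target)
        n = 10_000
        scene = SceneConfig(duration_s=15.0 * n, n_grazers=1)
        truth = simulate_trajectories(scene, behaviour, seed=99)
        freqs = np.bincount(truth.states[:-1, 0], minlength=3) / n
        se = np.sqrt(pi * (1 - pi) / n)
        assert (np.abs(freqs - pi) <= 3 * se).all()

    def test_displacements_stay_inside_generating_speed_band(self):
        scene = SceneConfig(duration_s=1800.0, n_grazers=6)
        behaviour = BehaviourModel()
        truth = simulate_trajectories(scene, behaviour, seed=7)
        dt_h = scene.frame_interval_s / 3600.0
        disp = np.linalg.norm(np.diff(truth.positions, axis=0), axis=2)
        speeds = disp / dt_h
        for s_idx, name in enumerate(STATE_NAMES):
            lo, hi = behaviour.speed_ranges[name]
            sel = truth.states[:-1] == s_idx
            assert (speeds[sel] >= lo - 1e-9).all()
            assert (speeds[sel] <= hi + 1e-9).all()

    def test_positions_always_inside_flume(self):
        scene = SceneConfig(duration_s=3600.0, n_grazers=8)
        truth = simulate_trajectories(scene, seed=21)
        assert (truth.positions[:, :, 0] >= 0).all()
        assert (truth.positions[:, :, 0] <= scene.flume_length_cm).all()
        assert (truth.positions[:, :, 1] >= 0).all()
        assert (truth.positions[:, :, 1] <= scene.flume_width_cm).all()

    def test_deterministic_under_fixed_seed(self):
        scene = SceneConfig(duration_s=600.0, n_grazers=4)
        a = simulate_trajectories(scene, seed=5)
        b = simulate_trajectories(scene, seed=5)
        assert np.array_equal(a.positions, b.positions)
        assert np.array_equal(a.states, b.states)
        assert a.trajectory_table().equals(b.trajectory_table())

    def test_non_stochastic_transition_matrix_rejected(self):
        with pytest.raises(ValueError):
            BehaviourModel(transition_matrix=np.array([[0.5, 0.5, 0.5]] * 3))

    def test_zero_px_per_cm_rejected(self):
        with pytest.raises(ValueError):
            SceneConfig(px_per_cm=0.0)

    def test_speed_support_on_classifier_boundary_rejected(self):
        with pytest.raises(ValueError):
            BehaviourModel(
                speed_ranges={"resting": (0.0, 0.4), "slow": (0.5, 3.8), "fast": (4.4, 10.0)}
            )


class TestRenderFrames:
    def test_no_grazers_means_no_grazing(self):
        scene = SceneConfig(duration_s=300.0, n_grazers=0)
        truth = simulate_trajectories(scene, seed=1)
        frames, masks = render_frames(truth, scene)
        assert masks.sum() == 0
        assert np.array_equal(frames[0], frames[-1])

    def test_stationary_grazer_matches_per_pixel_distance_oracle(self):
        scene = SceneConfig(duration_s=300.0, n_grazers=1)
        truth = simulate_trajectories(scene, rest_only_behaviour(), seed=13, initial_states="resting")
        _, masks = render_frames(truth, scene)
        x_px, y_px = truth.positions[0, 0] * scene.px_per_cm
        r = scene.mouth_radius_cm * scene.px_per_cm
        tile = scene.tile_mask()
        h, w = scene.frame_shape
        oracle = np.zeros((h, w), dtype=bool)
        for row in range(h):
            for col in range(w):
                if np.hypot(col - x_px, row - y_px) <= r and tile[row, col]:
                    oracle[row, col] = True
        assert np.array_equal(masks[-1], oracle)

    def test_marker_centre_pixel_is_exact_marker_colour(self, rendered_short):
        scene, truth, frames, _ = rendered_short
        pos_px = truth.positions_px()
        for g in range(truth.n_grazers):
            col = int(round(pos_px[0, g, 0]))
            row = int(round(pos_px[0, g, 1]))
            assert tuple(frames[0, row, col]) == tuple(scene.marker_rgb)

    def test_grazed_mask_monotone_over_time(self, rendered_short):
        _, _, _, masks = rendered_short
        for prev, cur in zip(masks, masks[1:]):
            assert (cur | prev == cur).all()

    def test_mask_equals_bare_pixels_when_markers_not_drawn(self, short_scene):
        truth = simulate_trajectories(short_scene, seed=4)
        frames, masks = render_frames(truth, short_scene, draw_markers=False)
        bare = np.asarray(short_scene.bare_rgb, dtype=np.uint8)
        rendered_bare = (frames[-1] == bare).all(axis=2)
        assert np.array_equal(rendered_bare, masks[-1])

    def test_marker_colour_collision_warns(self):
        scene = SceneConfig(duration_s=60.0, n_grazers=1, marker_rgb=(230, 230, 220))
        truth = simulate_trajectories(scene, seed=2)
        with pytest.warns(UserWarning, match="tolerance"):
            render_frames(truth, scene)

    def test_removed_tiles_excluded_from_substrate(self):
        full = SceneConfig()
        holey = SceneConfig(removed_tiles=(0, 7, 15, 22, 29, 12))
        assert holey.tile_mask().sum() < full.tile_mask().sum()
        # a grazer sitting on a removed tile leaves no grazed pixels there
        assert not (holey.tile_mask() & ~full.tile_mask()).any()


class TestAssayTables:
    def test_noiseless_single_group_sample_equals_ratio_row(self):
        F = default_pigment_library()
        cfg = AssayConfig(
            treatments=(TreatmentAssay("P-", 316, 0, 1.0, 0, 100.0, 0.0, 2),),
            ratio_matrix=F,
            noise_cv=0.0,
            chla_per_dry_mass=1.0,
        )
        _, pig, truth = generate_assay_tables(cfg, seed=0)
        # diatom share 100% and chl a == dry mass == 1 -> row equals ratio row
        assert np.allclose(pig.iloc[0].values, F.loc["diatoms"].values)
        assert truth["percent_diatoms"].iloc[0] == 100.0

    def test_same_seed_reproduces_tables_exactly(self):
        cfg = start_phase_assay()
        e1, p1, t1 = generate_assay_tables(cfg, seed=42)
        e2, p2, t2 = generate_assay_tables(cfg, seed=42)
        assert e1.equals(e2) and p1.equals(p2) and t1.equals(t2)

    def test_cp_sample_mean_within_clt_bound(self):
        # the P- molar C:P generator: mean 316, SD 68, n = 6 per table
        cfg = AssayConfig(treatments=(TreatmentAssay("P-", 316.0, 68.0, 0.72, 0.29, 94.0, 2.0, 6),))
        n_rep = 1000
        means = np.empty(n_rep)
        for k in range(n_rep):
            elem, _, _ = generate_assay_tables(cfg, seed=k)
            means[k] = elem["molar_cp"].mean()
        se = 68.0 / np.sqrt(6 * n_rep)
        assert abs(means.mean() - 316.0) <= 3 * se

    def test_elemental_row_cp_consistent_with_masses(self):
        from grazetrack.stats import molar_cp

        elem, _, _ = generate_assay_tables(start_phase_assay(), seed=8)
        for row in elem.itertuples():
            assert molar_cp(row.C_ug_per_cm2, row.P_ug_per_cm2) == pytest.approx(row.molar_cp)

    def test_negative_sd_rejected(self):
        with pytest.raises(ValueError):
            TreatmentAssay("P-", 316.0, -1.0, 0.72, 0.29, 94.0, 2.0, 6)
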