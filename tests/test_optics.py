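"""Organism motility models, rendering, and closed-loop sessions."""

import math

import numpy as np
import pytest

from trackscope.optics import (
    OpticsConfig,
    OrganismModel,
    OrganismState,
    SessionConfig,
    render_frame,
    run_session,
    step_organism,
)
from trackscope.stage import StageState
from trackscope.telemetry import write_csv


class TestStepOrganism:
    @pytest.mark.parametrize("kind", ["ballistic", "run_tumble", "stop_go", "circular_lurch", "drift"])
    def test_zero_speed_never_moves(self, kind, rng):
        model = OrganismModel(kind=kind, speed_um_s=0.0)
        state = OrganismState(x_um=5.0, y_um=-3.0)
        for _ in range(100):
            state = step_organism(model, state, 0.05, rng)
        assert (state.x_um, state.y_um) == (5.0, -3.0)

    def test_ballistic_advances_along_heading(self, rng):
        model = OrganismModel(kind="ballistic", speed_um_s=100.0)
        state = step_organism(model, OrganismState(heading_rad=0.0), 1.0, rng)
        assert state.x_um == pytest.approx(100.0)
        assert state.y_um == pytest.approx(0.0, abs=1e-9)

    def test_tumble_rate_matches_poisson_rate(self, rng):
        """Monte Carlo: observed tumbles/s within 3 SE of the 1 Hz rate."""
        model = OrganismModel(kind="run_tumble", speed_um_s=0.0, turn_rate_hz=1.0)
        state = OrganismState(heading_rad=0.123)
        dt, n = 0.01, 10_000
        tumbles = 0
        for _ in range(n):
            new = step_organism(model, state, dt, rng)
            if new.heading_rad != state.heading_rad:
                tumbles += 1
            state = new
        expected = n * (1.0 - math.exp(-1.0 * dt))
        se = math.sqrt(expected)
        assert abs(tumbles - expected) <= 3 * se

    def test_stop_go_dwell_rates(self, rng):
        model = OrganismModel(kind="stop_go", speed_um_s=100.0, dwell_exit_hz=(0.5, 1.0))
        state = OrganismState(moving=True)
        dt, n = 0.05, 40_000
        moving_time = 0.0
        for _ in range(n):
            state = step_organism(model, state, dt, rng)
            moving_time += dt if state.moving else 0.0
        # stationary fraction = r_m/(r_m+r_s) = 1/3 at equilibrium
        assert moving_time / (n * dt) == pytest.approx(2.0 / 3.0, abs=0.05)

    def test_circular_lurch_turns_at_bias_rate(self, rng):
        model = OrganismModel(kind="circular_lurch", speed_um_s=10.0, angular_bias_rad_s=0.5)
        state = OrganismState(heading_rad=0.0)
        state = step_organism(model, state, 0.1, rng)
        assert state.heading_rad == pytest.approx(0.05)

    def test_reflecting_walls_keep_organism_in_arena(self, rng):
        model = OrganismModel(kind="run_tumble", speed_um_s=500.0, turn_rate_hz=2.0)
        state = OrganismState(x_um=480.0, heading_rad=0.0)
        arena = (1000.0, 1000.0)
        for _ in range(2000):
            state = step_organism(model, state, 0.05, rng, arena)
            assert abs(state.x_um) <= 500.0 and abs(state.y_um) <= 500.0


class TestRenderFrame:
    def test_organism_at_stage_position_renders_centered(self, quiet_optics, ellipse_model):
        frame = render_frame(quiet_optics, ellipse_model, OrganismState(), StageState())
        fg = np.argwhere(frame < quiet_optics.background_level - 10)
        cy, cx = fg.mean(axis=0)
        assert cx == pytest.approx(320, abs=0.6)
        assert cy == pytest.approx(240, abs=0.6)

    def test_lateral_offset_maps_through_pixel_scale(self, quiet_optics, ellipse_model):
        org = OrganismState(x_um=100.0)
        frame = render_frame(quiet_optics, ellipse_model, org, StageState())
        fg = np.argwhere(frame < quiet_optics.background_level - 10)
        assert fg.mean(axis=0)[1] == pytest.approx(420, abs=0.6)

    def test_inverted_mount_flips_vertical_axis(self, ellipse_model):
        opt = OpticsConfig(noise_sigma=0.0, inverted_y=True)
        org = OrganismState(y_um=50.0)
        frame = render_frame(opt, ellipse_model, org, StageState())
        fg = np.argwhere(frame < opt.background_level - 10)
        assert fg.mean(axis=0)[0] == pytest.approx(190, abs=0.6)

    def test_far_away_organism_leaves_pure_background(self, quiet_optics, ellipse_model, rng):
        org = OrganismState(x_um=100_000.0)  # 10 cm away
        frame = render_frame(quiet_optics, ellipse_model, org, StageState())
        assert np.all(frame == int(quiet_optics.background_level))

    def test_dark_field_renders_bright_organism(self, ellipse_model):
        opt = OpticsConfig(noise_sigma=0.0, background_level=20.0, organism_contrast=150.0)
        frame = render_frame(opt, ellipse_model, OrganismState(), StageState())
        assert frame.max() >= 160 and frame.min() == 20

    def test_rendering_is_pure(self, optics, ellipse_model):
        f1 = render_frame(optics, ellipse_model, OrganismState(), StageState(), np.random.default_rng(3))
        f2 = render_frame(optics, ellipse_model, OrganismState(), StageState(), np.random.default_rng(3))
        assert np.array_equal(f1, f2)


class TestClosedLoop:
    def test_stationary_organism_needs_no_commands(self):
        model = OrganismModel(kind="ballistic", speed_um_s=0.0)
        res = run_session(SessionConfig(duration_s=10.0, seed=5), model, OpticsConfig())
        assert res.n_commands == 0
        assert res.in_view_fraction == 1.0
        # reconstruction stays within one pixel-equivalent of no motion
        assert max(abs(r.x_frame_px) + abs(r.y_frame_px) for r in res.records) <= 1

    def test_uncontrolled_ballistic_exits_in_predicted_time(self, quiet_optics, rng):
        """Without the controller a 500 um/s swimmer leaves the half-frame
        (320 px at 1 um/px) in about 0.64 s."""
        model = OrganismModel(kind="ballistic", speed_um_s=500.0)
        state = OrganismState(heading_rad=0.0)
        t, dt = 0.0, 0.01
        while abs(state.x_um) <= 320.0:
            state = step_organism(model, state, dt, rng)
            t += dt
        assert t == pytest.approx(320.0 / 500.0, rel=0.05)

    def test_controlled_ballistic_stays_in_view(self):
        model = OrganismModel(kind="ballistic", speed_um_s=500.0)
        res = run_session(SessionConfig(duration_s=30.0, seed=6), model, OpticsConfig())
        assert res.in_view_fraction >= 0.99
        assert res.n_commands > 0

    def test_identical_seeds_give_byte_identical_csv(self, tmp_path):
        model = OrganismModel(kind="run_tumble", speed_um_s=300.0)
        paths = []
        for name in ("a.csv", "b.csv"):
            res = run_session(SessionConfig(duration_s=5.0, seed=9), model, OpticsConfig())
            p = tmp_path / name
            write_csv(res.records, p)
            paths.append(p.read_bytes())
        assert paths[0] == paths[1]

    def test_ground_truth_speed_recovers_configured_speed(self):
        """Mean ground-truth speed of a run_tumble session matches the
        configured speed within 3 SE (tumbles do not change speed)."""
        model = OrganismModel(kind="run_tumble", speed_um_s=400.0, turn_rate_hz=0.5)
        res = run_session(SessionConfig(duration_s=30.0, seed=10), model, OpticsConfig())
        gt = res.ground_truth
        v = np.hypot(np.diff(gt.x_um), np.diff(gt.y_um)) / np.diff(gt.t_ms / 1000.0)
        # tumbles within a 50 ms bin shorten the chord slightly; 3% margin
        assert v.mean() == pytest.approx(400.0, rel=0.03)

    def test_telemetry_grid_is_50_ms(self):
        model = OrganismModel(kind="ballistic", speed_um_s=100.0)
        res = run_session(SessionConfig(duration_s=5.0, seed=11), model, OpticsConfig())
        t = [r.t_ms for r in res.records]
        assert t[0] == 0
        assert all(b - a == 50 for a, b in zip(t, t[1:]))
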