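"""Stage kinematics, command dialect and virtual-stage integration."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from trackscope.stage import (
    MICROSTEPS,
    CommandError,
    OrganismTooFastError,
    StageCommand,
    StageConfig,
    VirtualStage,
    decode_command,
    encode_command,
    max_speed_um_s,
    microns_to_steps,
    select_microstep,
    step_size_um,
    steps_to_microns,
)


class TestStepSize:
    @pytest.mark.parametrize(
        "cfg, expected",
        [
            (StageConfig(), 8000.0 / 1200.0),
            (StageConfig(microstep=32), 8000.0 / 1200.0 / 32.0),
            (StageConfig(gear_ratio=1.0), 20.0),
        ],
    )
    def test_examples(self, cfg, expected):
        assert step_size_um(cfg) == pytest.approx(expected, rel=1e-12)

    def test_strictly_decreasing_in_microstep(self):
        sizes = [step_size_um(StageConfig(microstep=m)) for m in MICROSTEPS]
        assert all(a > b for a, b in zip(sizes, sizes[1:]))

    def test_precision_gain_is_exactly_32(self):
        assert step_size_um(StageConfig(microstep=32)) * 32 == step_size_um(StageConfig())

    def test_invalid_microstep_rejected(self):
        with pytest.raises(ValueError):
            StageConfig(microstep=3)


class TestMicronsToSteps:
    @pytest.mark.parametrize(
        "d_um, cfg, expected",
        [
            (0.0, StageConfig(), 0),
            (8000.0, StageConfig(), 1200),
            (-3.3, StageConfig(microstep=32), -16),
        ],
    )
    def test_examples(self, d_um, cfg, expected):
        assert microns_to_steps(d_um, cfg) == expected

    def test_half_away_from_zero_symmetry(self):
        cfg = StageConfig()
        half = step_size_um(cfg) / 2.0
        assert microns_to_steps(half, cfg) == 1
        assert microns_to_steps(-half, cfg) == -1

    def test_rejects_non_finite(self):
        with pytest.raises(ValueError):
            microns_to_steps(float("nan"), StageConfig())

    @given(d=st.floats(-1e6, 1e6), m=st.sampled_from(MICROSTEPS))
    @settings(max_examples=500, deadline=None)
    def test_quantization_bound(self, d, m):
        cfg = StageConfig(microstep=m)
        back = steps_to_microns(microns_to_steps(d, cfg), cfg)
        assert abs(back - d) <= step_size_um(cfg) * (0.5 + 1e-9)


class TestSpeedModel:
    def test_calibrated_range_matches_instrument(self):
        # full steps ~4600 um/s; 1/32 gives 4600/32
        cfg = StageConfig()
        assert max_speed_um_s(cfg) == pytest.approx(4600.0)
        assert max_speed_um_s(cfg.with_microstep(32)) == pytest.approx(4600.0 / 32.0)

    @pytest.mark.parametrize("m", MICROSTEPS[:-1])
    def test_doubling_microstep_halves_speed(self, m):
        cfg = StageConfig(microstep=m)
        assert max_speed_um_s(cfg.with_microstep(2 * m)) == pytest.approx(max_speed_um_s(cfg) / 2)

    def test_zero_pulse_rate_means_zero_speed(self):
        assert max_speed_um_s(StageConfig(pulse_rate_hz=0.0)) == 0.0

    @pytest.mark.parametrize(
        "speed, expected",
        [(0.0, 32), (1000.0, 2), (2000.0, 1)],
    )
    def test_select_microstep(self, speed, expected):
        assert select_microstep(speed, StageConfig()) == expected

    def test_select_microstep_organism_too_fast(self):
        with pytest.raises(OrganismTooFastError):
            select_microstep(3000.0, StageConfig())


class TestCommandDialect:
    @pytest.mark.parametrize(
        "cmd, line",
        [
            (StageCommand("MOVE", "X", 1200, 800.0), "MOVE X 1200 F800\n"),
            (StageCommand("MOVE", "Y", -120, 690.5), "MOVE Y -120 F690.5\n"),
            (StageCommand("HALT"), "HALT\n"),
            (StageCommand("POS?"), "POS?\n"),
        ],
    )
    def test_encode_decode_round_trip(self, cmd, line):
        assert encode_command(cmd) == line
        assert decode_command(line) == cmd

    @pytest.mark.parametrize(
        "line",
        ["", "MOVE Z 5 F1", "MOVE X 5", "MOVE X five F1", "MOVE X 5 800", "JOG X 5 F1", "HALT NOW"],
    )
    def test_malformed_lines_rejected(self, line):
        with pytest.raises(CommandError):
            decode_command(line)

    def test_move_requires_positive_rate(self):
        with pytest.raises(CommandError):
            StageCommand("MOVE", "X", 10, 0.0)


class TestVirtualStage:
    def test_position_unchanged_without_command(self, stage_cfg):
        stage = VirtualStage(stage_cfg)
        stage.advance(1.0)
        assert stage.state.x_um == 0.0 and stage.state.y_um == 0.0

    def test_full_jog_completes_in_expected_time(self, stage_cfg):
        # 1200 steps at 1200 steps/s is rate-limited to the 690 Hz pulse
        # ceiling, so only part of the 8 mm jog completes in 1 s ...
        stage = VirtualStage(stage_cfg)
        assert stage.send_line("MOVE X 1200 F1200") == "OK"
        stage.advance(1.0)
        assert stage.state.x_um == pytest.approx(690 * step_size_um(stage_cfg))
        # ... and the rest by 1200/690 s
        stage.advance(1200 / 690 - 1.0 + 1e-6)
        assert stage.state.x_um == pytest.approx(8000.0)
        assert not stage.busy("X")

    def test_command_at_commanded_rate_below_ceiling(self, stage_cfg):
        stage = VirtualStage(stage_cfg)
        stage.submit(StageCommand("MOVE", "X", 600, 600.0))
        stage.advance(1.0 + 1e-9)
        assert stage.state.x_um == pytest.approx(600 * step_size_um(stage_cfg))

    def test_travel_limit_clips_and_flags(self, stage_cfg):
        stage = VirtualStage(stage_cfg)
        stage.submit(StageCommand("MOVE", "X", 30000, 690.0))  # 200 mm target
        for _ in range(100):
            stage.advance(1.0)
        assert stage.state.x_um == stage_cfg.travel_um
        assert stage.state.limit_hit

    def test_halt_clears_motion(self, stage_cfg):
        stage = VirtualStage(stage_cfg)
        stage.submit(StageCommand("MOVE", "Y", 1000, 500.0))
        stage.submit(StageCommand("HALT"))
        stage.advance(10.0)
        assert stage.state.y_um == 0.0 and stage.state.halted

    def test_pos_query_reports_position(self, stage_cfg):
        stage = VirtualStage(stage_cfg)
        assert stage.send_line("POS?") == "POS 0.000 0.000"

    def test_busy_axis_rejects_stacked_move(self, stage_cfg):
        stage = VirtualStage(stage_cfg)
        stage.submit(StageCommand("MOVE", "X", 1000, 100.0))
        assert stage.submit(StageCommand("MOVE", "X", 1000, 100.0)).startswith("ERR")

    @given(
        commands=st.lists(
            st.tuples(
                st.sampled_from(["MOVE", "HALT"]),
                st.sampled_from(["X", "Y"]),
                st.integers(-60000, 60000),
                st.floats(1.0, 5000.0),
            ),
            max_size=12,
        ),
        dts=st.lists(st.floats(0.01, 30.0), min_size=1, max_size=12),
    )
    @settings(max_examples=500, deadline=None)
    def test_never_exceeds_travel_or_speed(self, commands, dts):
        """Random command streams: position stays within limits and the
        distance covered per advance never exceeds max speed x dt."""
        cfg = StageConfig()
        stage = VirtualStage(cfg)
        vmax = max_speed_um_s(cfg)
        i = 0
        for dt in dts:
            if i < len(commands):
                verb, axis, steps, rate = commands[i]
                i += 1
                if verb == "HALT":
                    stage.submit(StageCommand("HALT"))
                else:
                    stage.submit(StageCommand("MOVE", axis, steps, rate))
            before = (stage.state.x_um, stage.state.y_um)
            stage.advance(dt)
            after = (stage.state.x_um, stage.state.y_um)
            assert abs(after[0]) <= cfg.travel_um and abs(after[1]) <= cfg.travel_um
            assert math.hypot(after[0] - before[0], after[1] - before[1]) <= (
                vmax * dt * math.sqrt(2) * (1 + 1e-9)
            )
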