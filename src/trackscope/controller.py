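"""Dead-zone visual servo: keep the tracked box inside a central zone.

The control law compares the bounding-box centre against a central zone
(a fraction of each frame dimension around the frame centre).  While the
centre stays inside the zone, no command is issued at all — the dead
zone prevents the stage from chattering around the exact centre when the
organism stops or pivots, or when the tracker's perceived centre
wanders.  Once the centre leaves the zone on an axis, a single
proportional jog re-centres the organism on that axis; a new correction
is only issued after the previous jog on the same axis completes, so
commands never stack.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np

from .stage import StageCommand, VirtualStage, max_speed_um_s, microns_to_steps, step_size_um
from .tracker import TrackerState, is_lost, update_tracker

__all__ = [
    "ZoneConfig",
    "ControllerConfig",
    "ControlCommand",
    "TickResult",
    "center_offset",
    "in_zone",
    "plan_correction",
    "control_tick",
]


@dataclass(frozen=True)
class ZoneConfig:
    """Geometry of the dead zone and the pixel-to-stage mapping.

    ``zone_fraction`` is the central zone's extent as a fraction of each
    frame dimension (1/3 by default: the middle third).  ``axis_sign``
    maps apparent pixel displacement to stage direction and absorbs the
    mount orientation; with the simulator's rendering convention
    (pixel offset = (organism - stage) / pixel_scale) the correct sign
    is -1 per axis, which makes the stage chase the organism.
    ``max_jog_um`` clips a single correction so a tracker glitch cannot
    fling the stage.
    """

    zone_fraction: float = 1.0 / 3.0
    axis_sign: Tuple[int, int] = (-1, -1)
    pixel_scale_um: float = 1.0
    max_jog_um: float = 2000.0

    def __post_init__(self) -> None:
        if not 0 < self.zone_fraction <= 1:
            raise ValueError("zone_fraction must be in (0, 1]")
        if any(s not in (-1, 1) for s in self.axis_sign):
            raise ValueError("axis_sign components must be -1 or +1")
        if self.pixel_scale_um <= 0 or self.max_jog_um <= 0:
            raise ValueError("pixel_scale_um and max_jog_um must be positive")


@dataclass(frozen=True)
class ControllerConfig:
    """Zone geometry plus stage-rate and loss policy."""

    zone: ZoneConfig = field(default_factory=ZoneConfig)
    rate_um_s: Optional[float] = None  # None -> stage maximum
    loss_threshold: float = 0.2


@dataclass(frozen=True)
class ControlCommand:
    """Planned per-axis jogs in micrometres (0 = leave the axis alone)."""

    jog_x_um: float
    jog_y_um: float
    rate_um_s: float


@dataclass
class TickResult:
    """Outcome of one control tick."""

    box_center: Tuple[float, float]
    offset_px: Tuple[float, float]
    lost: bool
    commands: List[StageCommand]
    stage_position_um: Tuple[float, float]


def center_offset(box, frame_w: int, frame_h: int) -> Tuple[float, float]:
    """Bounding-box centre relative to the frame centre, pixels."""
    cx, cy = box.center
    return (cx - frame_w / 2.0, cy - frame_h / 2.0)


def in_zone(offset_px: Tuple[float, float], zone: ZoneConfig, frame_w: int, frame_h: int) -> Tuple[bool, bool]:
    """Per-axis flags: is the centre within the dead zone on that axis?

    The zone boundary is inclusive: an offset exactly at
    ``zone_fraction * dim / 2`` still counts as inside.
    """
    half_x = zone.zone_fraction * frame_w / 2.0
    half_y = zone.zone_fraction * frame_h / 2.0
    return (abs(offset_px[0]) <= half_x, abs(offset_px[1]) <= half_y)


def plan_correction(
    offset_px: Tuple[float, float],
    zone: ZoneConfig,
    frame_w: int,
    frame_h: int,
    rate_um_s: float,
) -> ControlCommand:
    """Proportional jog back to the exact centre for out-of-zone axes.

    For an axis outside its zone the jog is
    ``-axis_sign * offset_px * pixel_scale_um`` clipped to
    ``max_jog_um``; in-zone axes get a zero jog.
    """
    inside = in_zone(offset_px, zone, frame_w, frame_h)
    jogs = []
    for i in range(2):
        if inside[i]:
            jogs.append(0.0)
            continue
        jog = -zone.axis_sign[i] * offset_px[i] * zone.pixel_scale_um
        jog = max(-zone.max_jog_um, min(zone.max_jog_um, jog))
        jogs.append(jog)
    return ControlCommand(jog_x_um=jogs[0], jog_y_um=jogs[1], rate_um_s=rate_um_s)


def control_tick(
    frame,
    tracker_state: TrackerState,
    stage: VirtualStage,
    cfg: ControllerConfig,
) -> TickResult:
    """One pass of the closed loop: track, compare to zone, command.

    On track loss the stage is halted and no further MOVE is issued; the
    session owner decides whether to re-initialise.  Otherwise each axis
    whose offset left the zone — and that has no jog already in flight —
    receives a single MOVE quantised to whole micro-steps.
    """
    frame = np.asarray(frame)
    frame_h, frame_w = frame.shape[:2]
    tracker_state, box = update_tracker(tracker_state, frame)
    st = stage.state
    commands: List[StageCommand] = []

    if is_lost(tracker_state, cfg.loss_threshold):
        halt = StageCommand(verb="HALT")
        stage.submit(halt)
        commands.append(halt)
        return TickResult(
            box_center=box.center,
            offset_px=center_offset(box, frame_w, frame_h),
            lost=True,
            commands=commands,
            stage_position_um=(st.x_um, st.y_um),
        )

    offset = center_offset(box, frame_w, frame_h)
    rate_um_s = cfg.rate_um_s if cfg.rate_um_s is not None else max_speed_um_s(stage.cfg)
    plan = plan_correction(offset, cfg.zone, frame_w, frame_h, rate_um_s)
    size = step_size_um(stage.cfg)
    rate_steps = rate_um_s / size
    for axis, jog in (("X", plan.jog_x_um), ("Y", plan.jog_y_um)):
        if jog == 0.0 or stage.busy(axis):
            continue
        steps = microns_to_steps(jog, stage.cfg)
        if steps == 0:
            continue
        cmd = StageCommand(verb="MOVE", axis=axis, steps=steps, rate=rate_steps)
        stage.submit(cmd)
        commands.append(cmd)
    return TickResult(
        box_center=box.center,
        offset_px=offset,
        lost=False,
        commands=commands,
        stage_position_um=(st.x_um, st.y_um),
    )
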