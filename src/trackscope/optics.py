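"""Virtual arena, organism motility models, camera rendering, sessions.

This is the synthetic-data generator that makes the whole closed loop
testable at desk scale: a point-mass organism with one of five motility
models moves in an 18 cm x 18 cm arena with reflecting walls, and a
virtual camera renders the 640x480 field of view that the stage position
currently covers.  Ground truth is known at every instant, so tracking,
control and reconstruction can all be scored exactly.

Motility models (phenomenological, matching behaviours seen in ciliates
and small metazoans at 10 um - 2 mm body size and 0.1 um/s - 2 mm/s):

``ballistic``
    straight swimming at constant speed (also ``drift`` for passive
    advection — identical kinematics, different reading).
``run_tumble``
    straight runs interrupted by Poisson-rate tumbles to a fresh uniform
    heading (bacterial-style run-and-tumble).
``stop_go``
    a two-state Markov switch between a moving and a stationary state
    (e.g. a stentorid alternating swimming and anchored feeding); the
    rendered ellipse rounds up while stationary, echoing the trumpet ->
    sphere shape change.
``circular_lurch``
    constant angular bias superimposed on forward motion (the clockwise
    circling of uncoordinated brine-shrimp nauplii).

Rendering is grayscale only: bright-field scenes are a high background
with a darker organism (negative contrast), dark-field the reverse.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np

from .controller import ControllerConfig, ZoneConfig, control_tick
from .stage import StageConfig, VirtualStage, select_microstep
from .telemetry import TrackRecord, Trajectory
from .tracker import BoundingBox, init_tracker

__all__ = [
    "OpticsConfig",
    "OrganismModel",
    "OrganismState",
    "SessionConfig",
    "SessionResult",
    "ORGANISM_KINDS",
    "step_organism",
    "render_frame",
    "true_bounding_box",
    "run_session",
]

ORGANISM_KINDS = ("ballistic", "run_tumble", "stop_go", "circular_lurch", "drift")


@dataclass(frozen=True)
class OpticsConfig:
    """Virtual camera: geometry, illumination and noise.

    ``pixel_scale_um`` is micrometres of sample per pixel (set by the
    magnification); the rendered field of view is therefore
    ``frame_w * pixel_scale_um`` across.  ``organism_contrast`` is the
    signed intensity offset of the organism against the background —
    negative for bright-field, positive for dark-field.  ``inverted_y``
    flips the vertical pixel axis for inverted-mount imaging.
    """

    frame_w: int = 640
    frame_h: int = 480
    pixel_scale_um: float = 1.0
    background_level: float = 200.0
    organism_contrast: float = -120.0
    noise_sigma: float = 3.0
    inverted_y: bool = False

    def __post_init__(self) -> None:
        if self.frame_w <= 0 or self.frame_h <= 0:
            raise ValueError("frame dimensions must be positive")
        if self.pixel_scale_um <= 0:
            raise ValueError("pixel_scale_um must be positive")


@dataclass(frozen=True)
class OrganismModel:
    """Ground-truth motility parameters.

    ``dwell_exit_hz`` are the two-state Markov exit rates of the
    ``stop_go`` model, (moving->stationary, stationary->moving); their
    reciprocals are the mean dwell times.  ``turn_rate_hz`` is the
    Poisson tumble rate of ``run_tumble``; ``angular_bias_rad_s`` the
    constant turning of ``circular_lurch``.  Body axes describe the
    rendered ellipse.
    """

    kind: str = "run_tumble"
    speed_um_s: float = 200.0
    turn_rate_hz: float = 0.5
    dwell_exit_hz: Tuple[float, float] = (0.25, 0.5)
    angular_bias_rad_s: float = 1.0
    body_long_um: float = 120.0
    body_short_um: float = 60.0

    def __post_init__(self) -> None:
        if self.kind not in ORGANISM_KINDS:
            raise ValueError(f"kind must be one of {ORGANISM_KINDS}")
        if self.speed_um_s < 0:
            raise ValueError("speed must be non-negative")
        if self.turn_rate_hz < 0 or any(r < 0 for r in self.dwell_exit_hz):
            raise ValueError("rates must be non-negative")
        if self.body_long_um <= 0 or self.body_short_um <= 0:
            raise ValueError("body axes must be positive")


@dataclass
class OrganismState:
    """Instantaneous kinematic state in arena coordinates."""

    x_um: float = 0.0
    y_um: float = 0.0
    heading_rad: float = 0.0
    moving: bool = True


@dataclass(frozen=True)
class SessionConfig:
    """Timing and reproducibility of one simulated tracking session.

    The control loop ticks at ``control_dt_s`` (30 Hz default — a
    conservative desktop tracking cadence); telemetry is emitted on the
    ``log_dt_ms`` grid (50 ms), linearly interpolated from tick samples
    when the grid is not a tick multiple.
    """

    duration_s: float = 60.0
    control_dt_s: float = 1.0 / 30.0
    log_dt_ms: float = 50.0
    seed: int = 0
    arena_um: Tuple[float, float] = (180_000.0, 180_000.0)

    def __post_init__(self) -> None:
        if self.duration_s <= 0 or self.control_dt_s <= 0 or self.log_dt_ms <= 0:
            raise ValueError("duration, control_dt and log_dt must be positive")


@dataclass
class SessionResult:
    """Everything a closed-loop run produces, plus its ground truth."""

    records: List[TrackRecord]
    ground_truth: Trajectory
    events: List[Tuple[float, str]]
    in_view_fraction: float
    n_commands: int
    n_ticks: int


# ---------------------------------------------------------------------------
# organism kinematics


def _reflect(value: float, lo: float, hi: float) -> Tuple[float, bool]:
    """Reflect a coordinate into [lo, hi]; True when a wall was hit."""
    hit = False
    span = hi - lo
    while value < lo or value > hi:
        hit = True
        if value < lo:
            value = 2 * lo - value
        else:
            value = 2 * hi - value
        if not math.isfinite(value) or span <= 0:
            return max(lo, min(hi, value)), True
    return value, hit


def step_organism(
    model: OrganismModel,
    state: OrganismState,
    dt: float,
    rng: np.random.Generator,
    arena_um: Tuple[float, float] = (180_000.0, 180_000.0),
) -> OrganismState:
    """Advance the motility model by *dt* seconds (returns a new state).

    Stochastic transitions (tumbles, stop/go switches) fire with
    probability ``1 - exp(-rate * dt)`` per step; walls reflect both the
    position and the heading.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    x, y, heading, moving = state.x_um, state.y_um, state.heading_rad, state.moving

    if model.kind == "run_tumble":
        if rng.random() < 1.0 - math.exp(-model.turn_rate_hz * dt):
            heading = rng.uniform(0.0, 2.0 * math.pi)
    elif model.kind == "stop_go":
        exit_rate = model.dwell_exit_hz[0] if moving else model.dwell_exit_hz[1]
        if rng.random() < 1.0 - math.exp(-exit_rate * dt):
            moving = not moving
            if moving:  # resume in a fresh direction
                heading = rng.uniform(0.0, 2.0 * math.pi)
    elif model.kind == "circular_lurch":
        heading += model.angular_bias_rad_s * dt

    if moving or model.kind not in ("stop_go",):
        step = model.speed_um_s * dt
        x += step * math.cos(heading)
        y += step * math.sin(heading)

    half_x, half_y = arena_um[0] / 2.0, arena_um[1] / 2.0
    x, hit_x = _reflect(x, -half_x, half_x)
    y, hit_y = _reflect(y, -half_y, half_y)
    if hit_x:
        heading = math.pi - heading
    if hit_y:
        heading = -heading
    return OrganismState(x_um=x, y_um=y, heading_rad=heading, moving=moving)


# ---------------------------------------------------------------------------
# rendering


def _pixel_position(optics: OpticsConfig, organism: OrganismState, stage_x: float, stage_y: float):
    sign = -1.0 if optics.inverted_y else 1.0
    px = (organism.x_um - stage_x) / optics.pixel_scale_um + optics.frame_w / 2.0
    py = sign * (organism.y_um - stage_y) / optics.pixel_scale_um + optics.frame_h / 2.0
    return px, py


def _body_axes_px(optics: OpticsConfig, model: OrganismModel, moving: bool) -> Tuple[float, float]:
    if model.kind == "stop_go" and not moving:
        # anchored/feeding form: equal-area circle instead of the ellipse
        r = math.sqrt(model.body_long_um * model.body_short_um) / 2.0
        a = b = r / optics.pixel_scale_um
    else:
        a = model.body_long_um / 2.0 / optics.pixel_scale_um
        b = model.body_short_um / 2.0 / optics.pixel_scale_um
    return max(a, 0.5), max(b, 0.5)


def render_frame(
    optics: OpticsConfig,
    model: OrganismModel,
    organism: OrganismState,
    stage_state,
    rng: Optional[np.random.Generator] = None,
    noise: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Render the current field of view as a uint8 grayscale frame.

    The organism is an anti-aliased ellipse (soft one-pixel edge) of
    intensity ``background + contrast`` centred at its apparent pixel
    position.  Gaussian read noise is added when *rng* is given; a
    pre-drawn zero-mean unit-variance field may be supplied as *noise*
    instead (the session runner recycles a bank of such fields, which
    is much cheaper than drawing 300k Gaussians per frame).  Rendering
    is pure: identical states, configs and generator state yield
    identical frames.
    """
    h, w = optics.frame_h, optics.frame_w
    if noise is not None and optics.noise_sigma > 0:
        frame = noise * np.float32(optics.noise_sigma)
        frame += np.float32(optics.background_level)
    elif rng is not None and optics.noise_sigma > 0:
        frame = rng.standard_normal((h, w), dtype=np.float32)
        frame *= optics.noise_sigma
        frame += optics.background_level
    else:
        frame = np.full((h, w), optics.background_level, dtype=np.float32)

    sx = stage_state.x_um if hasattr(stage_state, "x_um") else float(stage_state[0])
    sy = stage_state.y_um if hasattr(stage_state, "y_um") else float(stage_state[1])
    cx, cy = _pixel_position(optics, organism, sx, sy)
    a, b = _body_axes_px(optics, model, organism.moving)
    extent = max(a, b) + 2.0

    x0 = max(0, int(math.floor(cx - extent)))
    x1 = min(w, int(math.ceil(cx + extent)) + 1)
    y0 = max(0, int(math.floor(cy - extent)))
    y1 = min(h, int(math.ceil(cy + extent)) + 1)
    if x0 < x1 and y0 < y1:
        ys, xs = np.mgrid[y0:y1, x0:x1]
        dx = xs - cx
        dy = ys - cy
        theta = organism.heading_rad * (-1.0 if optics.inverted_y else 1.0)
        ct, st = math.cos(theta), math.sin(theta)
        u = dx * ct + dy * st
        v = -dx * st + dy * ct
        r = np.hypot(u / a, v / b)
        # soft edge ~1 px wide for anti-aliasing
        edge = 1.0 / max(min(a, b), 1.0)
        cover = np.clip((1.0 - r) / edge + 0.5, 0.0, 1.0)
        frame[y0:y1, x0:x1] += (optics.organism_contrast * cover).astype(np.float32)
    np.clip(frame, 0.0, 255.0, out=frame)
    return frame.astype(np.uint8)


def true_bounding_box(
    optics: OpticsConfig, model: OrganismModel, organism: OrganismState, stage_state, margin_px: float = 3.0
) -> BoundingBox:
    """Ground-truth bounding box of the rendered ellipse, with margin."""
    sx = stage_state.x_um if hasattr(stage_state, "x_um") else float(stage_state[0])
    sy = stage_state.y_um if hasattr(stage_state, "y_um") else float(stage_state[1])
    cx, cy = _pixel_position(optics, organism, sx, sy)
    a, b = _body_axes_px(optics, model, organism.moving)
    theta = organism.heading_rad
    half_w = math.hypot(a * math.cos(theta), b * math.sin(theta)) + margin_px
    half_h = math.hypot(a * math.sin(theta), b * math.cos(theta)) + margin_px
    x = max(0.0, cx - half_w)
    y = max(0.0, cy - half_h)
    x2 = min(float(optics.frame_w), cx + half_w)
    y2 = min(float(optics.frame_h), cy + half_h)
    return BoundingBox(x=x, y=y, w=max(x2 - x, 1.0), h=max(y2 - y, 1.0))


# ---------------------------------------------------------------------------
# closed-loop session


def _quantize_um(v: float) -> float:
    """Snap to the telemetry dialect's 3-decimal resolution."""
    return float(f"{v:.3f}")


def run_session(
    session: SessionConfig,
    model: OrganismModel,
    optics: OpticsConfig,
    stage_cfg: Optional[StageConfig] = None,
    controller_cfg: Optional[ControllerConfig] = None,
    tracker_backend: str = "native",
) -> SessionResult:
    """Run the full closed loop against the virtual stage and camera.

    Per control tick: render the current view, update the tracker, let
    the dead-zone controller issue stage jogs, integrate the stage, then
    advance the organism.  The tracker is initialised on the first frame
    with the true bounding box (standing in for the user's ROI click).
    Telemetry and synchronized ground truth are emitted on the
    ``log_dt_ms`` grid.  Deterministic for a fixed session seed.

    When no ``stage_cfg`` is given, the micro-stepping setting is chosen
    from the organism's nominal speed by the 2x rule.
    """
    if stage_cfg is None:
        base = StageConfig()
        stage_cfg = base.with_microstep(select_microstep(model.speed_um_s, base))
    if controller_cfg is None:
        controller_cfg = ControllerConfig(
            zone=ZoneConfig(pixel_scale_um=optics.pixel_scale_um)
        )

    rng = np.random.default_rng(session.seed)
    stage = VirtualStage(stage_cfg)
    organism = OrganismState(heading_rad=float(rng.uniform(0.0, 2.0 * math.pi)))

    # Noise bank: a handful of independent Gaussian fields, re-used with a
    # random cyclic shift per frame.  Marginally identical to fresh noise
    # and spatially white, at a fraction of the generation cost.
    bank = None
    if optics.noise_sigma > 0:
        bank = rng.standard_normal((8, optics.frame_h, optics.frame_w), dtype=np.float32)

    def _noise_field():
        if bank is None:
            return None
        i = int(rng.integers(bank.shape[0]))
        dy = int(rng.integers(optics.frame_h))
        dx = int(rng.integers(optics.frame_w))
        return np.roll(bank[i], (dy, dx), axis=(0, 1))

    first_frame = render_frame(optics, model, organism, stage.state, noise=_noise_field())
    roi = true_bounding_box(optics, model, organism, stage.state)
    tracker_state = init_tracker(first_frame, roi, backend_id=tracker_backend)

    n_ticks = max(2, int(round(session.duration_s / session.control_dt_s)))
    tick_t_ms = np.empty(n_ticks)
    tick_offset = np.empty((n_ticks, 2))
    tick_stage = np.empty((n_ticks, 2))
    tick_truth = np.empty((n_ticks, 2))
    events: List[Tuple[float, str]] = []
    in_view = 0
    n_commands = 0
    lost_logged = False
    limit_logged = False

    frame = first_frame
    for k in range(n_ticks):
        t_s = k * session.control_dt_s
        if k > 0:
            frame = render_frame(optics, model, organism, stage.state, noise=_noise_field())
        result = control_tick(frame, tracker_state, stage, controller_cfg)
        n_commands += sum(1 for c in result.commands if c.verb == "MOVE")

        if result.lost and not lost_logged:
            events.append((t_s * 1000.0, "track lost; stage halted"))
            lost_logged = True
        if stage.state.limit_hit and not limit_logged:
            events.append((t_s * 1000.0, "travel limit reached"))
            limit_logged = True

        tick_t_ms[k] = t_s * 1000.0
        tick_offset[k] = result.offset_px
        tick_stage[k] = (stage.state.x_um, stage.state.y_um)
        tick_truth[k] = (organism.x_um, organism.y_um)

        px, py = _pixel_position(optics, organism, stage.state.x_um, stage.state.y_um)
        if 0.0 <= px < optics.frame_w and 0.0 <= py < optics.frame_h:
            in_view += 1

        stage.advance(session.control_dt_s)
        organism = step_organism(model, organism, session.control_dt_s, rng, session.arena_um)

    # resample onto the telemetry grid
    grid_ms = np.arange(0.0, tick_t_ms[-1] + 1e-9, session.log_dt_ms)
    records = []
    gx = np.interp(grid_ms, tick_t_ms, tick_truth[:, 0])
    gy = np.interp(grid_ms, tick_t_ms, tick_truth[:, 1])
    ox = np.interp(grid_ms, tick_t_ms, tick_offset[:, 0])
    oy = np.interp(grid_ms, tick_t_ms, tick_offset[:, 1])
    sx = np.interp(grid_ms, tick_t_ms, tick_stage[:, 0])
    sy = np.interp(grid_ms, tick_t_ms, tick_stage[:, 1])
    for i, t in enumerate(grid_ms):
        records.append(
            TrackRecord(
                t_ms=int(round(t)),
                x_frame_px=int(round(ox[i])),
                y_frame_px=int(round(oy[i])),
                x_stage_um=_quantize_um(sx[i]),
                y_stage_um=_quantize_um(sy[i]),
            )
        )
    truth = Trajectory(
        t_ms=grid_ms,
        x_um=gx - gx[0],
        y_um=gy - gy[0],
        pixel_scale_um=optics.pixel_scale_um,
    )
    return SessionResult(
        records=records,
        ground_truth=truth,
        events=events,
        in_view_fraction=in_view / n_ticks,
        n_commands=n_commands,
        n_ticks=n_ticks,
    )
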