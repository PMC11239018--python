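"""Stepper/lead-screw XY-stage kinematics and a virtual stage.

The physical stage couples a NEMA 17 stepper (400 full steps per
revolution, 0.9 degree step angle) through a 3:1 pulley reduction to an
8 mm lead screw, so one full motor step translates the platform by
``8000 / (400 * 3) = 6.667`` micrometres.  Micro-stepping subdivides the
full step by 2..32, trading top speed for positional resolution: the
driver sustains a fixed pulse rate, so halving the step size halves the
maximum platform speed.  With the default calibration the platform runs
at about 4600 um/s at full steps down to about 144 um/s at 1/32
micro-stepping, which brackets organisms from fast ciliates to amoebae.

The :class:`VirtualStage` executes the same newline-terminated ASCII
command dialect a serial-attached controller would (``MOVE X -120 F800``,
``HALT``, ``POS?``), advancing its position in simulated time with speed
and travel-limit clamping, so the whole control loop can run without
hardware.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

__all__ = [
    "MICROSTEPS",
    "AXES",
    "StageConfig",
    "StageCommand",
    "StageState",
    "AxisJog",
    "VirtualStage",
    "OrganismTooFastError",
    "CommandError",
    "step_size_um",
    "microns_to_steps",
    "steps_to_microns",
    "max_speed_um_s",
    "select_microstep",
    "encode_command",
    "decode_command",
]

#: Micro-stepping divisors the driver supports.
MICROSTEPS = (1, 2, 4, 8, 16, 32)

#: Motorised axes. Z is manual on the instrument and is not modelled.
AXES = ("X", "Y")


class OrganismTooFastError(ValueError):
    """No micro-stepping setting reaches twice the organism's speed."""


class CommandError(ValueError):
    """Malformed stage command line."""


@dataclass(frozen=True)
class StageConfig:
    """Geometry and driver limits of one stepper/lead-screw axis pair.

    Parameters
    ----------
    steps_per_rev : int
        Full motor steps per motor revolution (400 for a 0.9 degree motor).
    microstep : int
        Micro-stepping divisor, one of :data:`MICROSTEPS`.
    gear_ratio : float
        Motor revolutions per lead-screw revolution (3:1 pulleys).
    lead_um : float
        Linear travel per screw revolution, micrometres (8 mm screw).
    travel_um : float
        Maximum travel per axis, micrometres, measured from the session
        origin; 180 000 um per axis gives the 18 cm x 18 cm tracking area.
    pulse_rate_hz : float
        Maximum sustained step-pulse frequency of the driver.  This is a
        calibration constant: 690 Hz reproduces the measured ~4600 um/s
        top speed at full steps with the default geometry.
    """

    steps_per_rev: int = 400
    microstep: int = 1
    gear_ratio: float = 3.0
    lead_um: float = 8000.0
    travel_um: float = 180_000.0
    pulse_rate_hz: float = 690.0

    def __post_init__(self) -> None:
        if self.steps_per_rev <= 0:
            raise ValueError("steps_per_rev must be positive")
        if self.microstep not in MICROSTEPS:
            raise ValueError(f"microstep must be one of {MICROSTEPS}, got {self.microstep}")
        if self.gear_ratio <= 0 or self.lead_um <= 0 or self.travel_um <= 0:
            raise ValueError("gear_ratio, lead_um and travel_um must be positive")
        if self.pulse_rate_hz < 0:
            raise ValueError("pulse_rate_hz must be non-negative")

    def with_microstep(self, microstep: int) -> "StageConfig":
        return replace(self, microstep=microstep)


def step_size_um(cfg: StageConfig) -> float:
    """Linear travel of one micro-step, micrometres.

    ``lead_um / (steps_per_rev * gear_ratio * microstep)`` — 6.667 um at
    full steps with defaults, 0.208 um at 1/32 micro-stepping.
    """
    return cfg.lead_um / (cfg.steps_per_rev * cfg.gear_ratio * cfg.microstep)


def microns_to_steps(d_um: float, cfg: StageConfig) -> int:
    """Quantize a displacement to whole micro-steps.

    Rounds half away from zero so that symmetric jogs map to symmetric
    step counts.
    """
    if not math.isfinite(d_um):
        raise ValueError("displacement must be finite")
    s = step_size_um(cfg)
    return int(math.copysign(math.floor(abs(d_um) / s + 0.5), d_um))


def steps_to_microns(steps: int, cfg: StageConfig) -> float:
    """Exact linear travel of a signed micro-step count."""
    return steps * step_size_um(cfg)


def max_speed_um_s(cfg: StageConfig) -> float:
    """Maximum platform speed: pulse rate times micro-step size.

    The driver's sustained pulse frequency is independent of the
    micro-stepping divisor, so speed scales as ``1/microstep``.
    """
    return cfg.pulse_rate_hz * step_size_um(cfg)


def select_microstep(organism_speed_um_s: float, cfg: StageConfig) -> int:
    """Pick the finest micro-stepping whose top speed covers the organism.

    The instrument's rule of thumb is to run the stage at at least twice
    the organism's speed; among the settings that satisfy that, the
    largest divisor (finest resolution) is chosen.

    Raises
    ------
    OrganismTooFastError
        If even full stepping cannot reach twice the organism's speed.
    """
    if organism_speed_um_s < 0:
        raise ValueError("organism speed must be non-negative")
    required = 2.0 * organism_speed_um_s
    for m in sorted(MICROSTEPS, reverse=True):
        if max_speed_um_s(cfg.with_microstep(m)) >= required:
            return m
    raise OrganismTooFastError(
        f"organism too fast: 2 x {organism_speed_um_s} um/s exceeds "
        f"{max_speed_um_s(cfg.with_microstep(1))} um/s at full steps"
    )


# ---------------------------------------------------------------------------
# Command dialect


@dataclass(frozen=True)
class StageCommand:
    """One line of the stage dialect.

    ``MOVE`` jogs an axis by a signed number of micro-steps at a pulse
    rate (steps/s); ``HALT`` cancels all motion; ``POS?`` queries the
    position.
    """

    verb: str
    axis: Optional[str] = None
    steps: int = 0
    rate: float = 0.0

    def __post_init__(self) -> None:
        if self.verb not in ("MOVE", "HALT", "POS?"):
            raise CommandError(f"unknown verb {self.verb!r}")
        if self.verb == "MOVE":
            if self.axis not in AXES:
                raise CommandError(f"MOVE requires axis in {AXES}, got {self.axis!r}")
            if self.rate <= 0:
                raise CommandError("MOVE requires rate > 0")


def _format_rate(rate: float) -> str:
    return f"{int(rate)}" if float(rate).is_integer() else f"{rate:g}"


def encode_command(cmd: StageCommand) -> str:
    """Serialize to a newline-terminated ASCII line."""
    if cmd.verb == "MOVE":
        return f"MOVE {cmd.axis} {cmd.steps} F{_format_rate(cmd.rate)}\n"
    return f"{cmd.verb}\n"


def decode_command(line: str) -> StageCommand:
    """Parse one dialect line; raises :class:`CommandError` on any defect."""
    parts = line.strip().split()
    if not parts:
        raise CommandError("empty command line")
    verb = parts[0]
    if verb in ("HALT", "POS?"):
        if len(parts) != 1:
            raise CommandError(f"{verb} takes no arguments: {line!r}")
        return StageCommand(verb=verb)
    if verb == "MOVE":
        if len(parts) != 4:
            raise CommandError(f"MOVE needs axis, steps and Frate: {line!r}")
        axis = parts[1]
        if axis not in AXES:
            raise CommandError(f"no such axis {axis!r}")
        try:
            steps = int(parts[2])
        except ValueError:
            raise CommandError(f"bad step count {parts[2]!r}") from None
        if not parts[3].startswith("F"):
            raise CommandError(f"rate field must start with 'F': {parts[3]!r}")
        try:
            rate = float(parts[3][1:])
        except ValueError:
            raise CommandError(f"bad rate {parts[3]!r}") from None
        return StageCommand(verb="MOVE", axis=axis, steps=steps, rate=rate)
    raise CommandError(f"unknown verb {verb!r}")


# ---------------------------------------------------------------------------
# Virtual stage


@dataclass
class AxisJog:
    """An in-flight jog: absolute target and linear rate."""

    target_um: float
    rate_um_s: float


@dataclass
class StageState:
    """Evolving platform position, signed micrometres from session origin."""

    x_um: float = 0.0
    y_um: float = 0.0
    jogs: dict = field(default_factory=dict)  # axis -> AxisJog
    halted: bool = False
    limit_hit: bool = False

    def position_um(self, axis: str) -> float:
        return self.x_um if axis == "X" else self.y_um

    def _set_position(self, axis: str, value: float) -> None:
        if axis == "X":
            self.x_um = value
        else:
            self.y_um = value


class VirtualStage:
    """Executes the command dialect against simulated kinematics.

    Position changes only through :meth:`advance`; commands set targets.
    Motion is clamped to the commanded rate, the driver's pulse-rate
    ceiling, and the per-axis travel limits.  Running into a limit sets
    ``state.limit_hit`` and completes the jog there.
    """

    def __init__(self, cfg: StageConfig, state: Optional[StageState] = None):
        self.cfg = cfg
        self.state = state if state is not None else StageState()

    # -- command interface ---------------------------------------------------

    def busy(self, axis: str) -> bool:
        """True while a jog is in flight on *axis*."""
        return axis in self.state.jogs

    def submit(self, cmd: StageCommand) -> str:
        """Execute a parsed command, returning the acknowledgment line."""
        st = self.state
        if cmd.verb == "HALT":
            st.jogs.clear()
            st.halted = True
            return "OK"
        if cmd.verb == "POS?":
            return f"POS {st.x_um:.3f} {st.y_um:.3f}"
        # MOVE
        if self.busy(cmd.axis):
            return f"ERR busy {cmd.axis}"
        size = step_size_um(self.cfg)
        rate_um_s = min(cmd.rate, self.cfg.pulse_rate_hz) * size
        target = st.position_um(cmd.axis) + cmd.steps * size
        st.jogs[cmd.axis] = AxisJog(target_um=target, rate_um_s=rate_um_s)
        st.halted = False
        return "OK"

    def send_line(self, line: str) -> str:
        """Byte-stream entry point: decode then submit; ERR on bad input."""
        try:
            cmd = decode_command(line)
        except CommandError as exc:
            return f"ERR {exc}"
        return self.submit(cmd)

    # -- time integration ----------------------------------------------------

    def advance(self, dt: float) -> None:
        """Integrate all in-flight jogs over *dt* seconds."""
        if dt <= 0:
            raise ValueError("dt must be positive")
        st = self.state
        lim = self.cfg.travel_um
        for axis in list(st.jogs):
            jog = st.jogs[axis]
            pos = st.position_um(axis)
            budget = jog.rate_um_s * dt
            delta = jog.target_um - pos
            move = math.copysign(min(abs(delta), budget), delta)
            new = pos + move
            if new > lim:
                new = lim
                st.limit_hit = True
                del st.jogs[axis]
            elif new < -lim:
                new = -lim
                st.limit_hit = True
                del st.jogs[axis]
            elif abs(jog.target_um - new) < 1e-9:
                new = min(max(jog.target_um, -lim), lim)
                del st.jogs[axis]
            st._set_position(axis, new)
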