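"""Run configuration: one YAML file describing a whole session.

Nested sections mirror the modules (``stage``, ``optics``,
``controller``, ``tracker``, ``session`` — with the organism model under
``session.organism`` — and ``analysis``).  Every field has a default, so
an empty file is a valid run; unknown keys are rejected with their full
dotted path, and cross-field sanity checks (stage top speed versus the
2x organism-speed rule) are applied at load time.
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass, field
from typing import Optional, Union

import yaml

from .controller import ControllerConfig, ZoneConfig
from .optics import OpticsConfig, OrganismModel, SessionConfig
from .stage import StageConfig, max_speed_um_s, select_microstep

__all__ = ["RunConfig", "AnalysisConfig", "TrackerChoice", "ConfigError", "load_config", "config_from_dict"]


class ConfigError(ValueError):
    """Bad run configuration; the message names the offending key."""


@dataclass(frozen=True)
class TrackerChoice:
    backend: str = "native"

    def __post_init__(self) -> None:
        if self.backend not in ("native", "csrt"):
            raise ConfigError(f"tracker.backend must be 'native' or 'csrt', got {self.backend!r}")


@dataclass(frozen=True)
class AnalysisConfig:
    """Defaults for the analyze workflow."""

    window: int = 5
    v_on_um_s: float = 50.0
    v_off_um_s: float = 25.0
    min_dwell_ms: float = 250.0
    body_length_um: Optional[float] = None


@dataclass(frozen=True)
class RunConfig:
    stage: StageConfig = field(default_factory=StageConfig)
    optics: OpticsConfig = field(default_factory=OpticsConfig)
    controller: ControllerConfig = field(default_factory=ControllerConfig)
    tracker: TrackerChoice = field(default_factory=TrackerChoice)
    session: SessionConfig = field(default_factory=SessionConfig)
    organism: OrganismModel = field(default_factory=OrganismModel)
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)


_SCHEMA = {
    "stage": {"steps_per_rev", "microstep", "gear_ratio", "lead_um", "travel_um", "pulse_rate_hz"},
    "optics": {
        "frame_w",
        "frame_h",
        "pixel_scale_um",
        "background_level",
        "organism_contrast",
        "noise_sigma",
        "inverted_y",
    },
    "controller": {"zone_fraction", "axis_sign", "pixel_scale_um", "max_jog_um", "rate_um_s", "loss_threshold"},
    "tracker": {"backend"},
    "session": {"duration_s", "control_dt_s", "log_dt_ms", "seed", "arena_um", "organism"},
    "organism": {
        "kind",
        "speed_um_s",
        "turn_rate_hz",
        "dwell_exit_hz",
        "angular_bias_rad_s",
        "body_long_um",
        "body_short_um",
    },
    "analysis": {"window", "v_on_um_s", "v_off_um_s", "min_dwell_ms", "body_length_um"},
}


def _check_keys(section: str, data: dict) -> None:
    if not isinstance(data, dict):
        raise ConfigError(f"section {section!r} must be a mapping")
    for key in data:
        if key not in _SCHEMA[section]:
            raise ConfigError(f"unknown key {section}.{key}")


def _pair(value, key: str):
    if not isinstance(value, (list, tuple)) or len(value) != 2:
        raise ConfigError(f"{key} must be a 2-element list")
    return tuple(value)


def config_from_dict(data: Optional[dict]) -> RunConfig:
    """Build a validated :class:`RunConfig` from a (possibly empty) dict.

    ``stage.microstep`` may be the string ``"auto"`` to let the loader
    pick the finest setting that still reaches twice the configured
    organism speed.
    """
    data = data or {}
    if not isinstance(data, dict):
        raise ConfigError("configuration root must be a mapping")
    for key in data:
        if key not in ("stage", "optics", "controller", "tracker", "session", "analysis"):
            raise ConfigError(f"unknown section {key!r}")

    session_raw = dict(data.get("session") or {})
    _check_keys("session", session_raw)
    organism_raw = dict(session_raw.pop("organism", None) or {})
    _check_keys("organism", organism_raw)
    if "dwell_exit_hz" in organism_raw:
        organism_raw["dwell_exit_hz"] = _pair(organism_raw["dwell_exit_hz"], "session.organism.dwell_exit_hz")
    if "arena_um" in session_raw:
        session_raw["arena_um"] = _pair(session_raw["arena_um"], "session.arena_um")

    try:
        organism = OrganismModel(**organism_raw)
        session = SessionConfig(**session_raw)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"session: {exc}") from None

    stage_raw = dict(data.get("stage") or {})
    _check_keys("stage", stage_raw)
    auto_microstep = stage_raw.get("microstep") == "auto"
    if auto_microstep:
        stage_raw.pop("microstep")
    try:
        stage = StageConfig(**stage_raw)
        if auto_microstep:
            stage = stage.with_microstep(select_microstep(organism.speed_um_s, stage))
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"stage: {exc}") from None

    optics_raw = dict(data.get("optics") or {})
    _check_keys("optics", optics_raw)
    try:
        optics = OpticsConfig(**optics_raw)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"optics: {exc}") from None

    controller_raw = dict(data.get("controller") or {})
    _check_keys("controller", controller_raw)
    zone_kwargs = {}
    for k in ("zone_fraction", "axis_sign", "max_jog_um", "pixel_scale_um"):
        if k in controller_raw:
            zone_kwargs[k] = controller_raw.pop(k)
    if "axis_sign" in zone_kwargs:
        zone_kwargs["axis_sign"] = _pair(zone_kwargs["axis_sign"], "controller.axis_sign")
    zone_kwargs.setdefault("pixel_scale_um", optics.pixel_scale_um)
    try:
        controller = ControllerConfig(zone=ZoneConfig(**zone_kwargs), **controller_raw)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"controller: {exc}") from None

    tracker_raw = dict(data.get("tracker") or {})
    _check_keys("tracker", tracker_raw)
    tracker = TrackerChoice(**tracker_raw)

    analysis_raw = dict(data.get("analysis") or {})
    _check_keys("analysis", analysis_raw)
    try:
        analysis = AnalysisConfig(**analysis_raw)
    except TypeError as exc:
        raise ConfigError(f"analysis: {exc}") from None

    cfg = RunConfig(
        stage=stage,
        optics=optics,
        controller=controller,
        tracker=tracker,
        session=session,
        organism=organism,
        analysis=analysis,
    )
    _cross_checks(cfg)
    return cfg


def _cross_checks(cfg: RunConfig) -> None:
    top = max_speed_um_s(cfg.stage)
    if top < 2.0 * cfg.organism.speed_um_s:
        warnings.warn(
            f"stage top speed {top:.0f} um/s is below twice the organism speed "
            f"({cfg.organism.speed_um_s:.0f} um/s); tracking may fall behind "
            "(consider a coarser microstep setting)",
            stacklevel=3,
        )


def load_config(path: Union[str, os.PathLike, None]) -> RunConfig:
    """Load a YAML run configuration; ``None`` yields all defaults."""
    if path is None:
        return config_from_dict({})
    with open(path) as fh:
        try:
            data = yaml.safe_load(fh)
        except yaml.YAMLError as exc:
            raise ConfigError(f"invalid YAML: {exc}") from None
    return config_from_dict(data)
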