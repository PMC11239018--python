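"""Speeds, distances, BL/s normalisation and moving/stationary segmentation.

Works on reconstructed trajectories sampled at the 50 ms telemetry
cadence (uneven sampling is handled by duration weighting).  Speeds are
forward differences assigned to interval midpoints, optionally smoothed
with a centred moving average; the default 5-sample window (250 ms at
the 50 ms cadence) suppresses the quantisation spikes left by discrete
stage jogs without hiding genuine stop/start events.

Moving/stationary segmentation uses hysteresis (enter "moving" above
``v_on``, leave below ``v_off`` with ``v_off <= v_on``) so speed noise
around a single threshold cannot shred a bout into fragments; segments
shorter than a minimum dwell are merged into their longer neighbour.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List

import numpy as np

from .telemetry import Trajectory

__all__ = [
    "SpeedSeries",
    "SpeedSummary",
    "StateSegment",
    "speeds",
    "summarize",
    "body_lengths_per_second",
    "segment_motion",
]


@dataclass(frozen=True)
class SpeedSeries:
    """Instantaneous speeds at interval midpoints.

    ``dt_s`` holds per-interval durations for duration weighting;
    ``window`` records the smoothing window applied (1 = none).
    """

    t_ms: np.ndarray
    speed_um_s: np.ndarray
    raw_um_s: np.ndarray
    dt_s: np.ndarray
    window: int

    def __len__(self) -> int:
        return len(self.speed_um_s)


@dataclass(frozen=True)
class SpeedSummary:
    mean_um_s: float
    max_um_s: float
    median_um_s: float
    q1_um_s: float
    q3_um_s: float
    total_distance_um: float
    duration_s: float

    def as_dict(self) -> dict:
        return {
            "mean_um_s": self.mean_um_s,
            "max_um_s": self.max_um_s,
            "median_um_s": self.median_um_s,
            "q1_um_s": self.q1_um_s,
            "q3_um_s": self.q3_um_s,
            "total_distance_um": self.total_distance_um,
            "duration_s": self.duration_s,
        }


@dataclass(frozen=True)
class StateSegment:
    """A maximal run of one behavioural state, [t_start, t_end) ms."""

    state: str  # "moving" | "stationary"
    t_start_ms: float
    t_end_ms: float

    @property
    def duration_ms(self) -> float:
        return self.t_end_ms - self.t_start_ms


def _moving_average(values: np.ndarray, window: int) -> np.ndarray:
    """Centred moving average with truncated edges."""
    if window == 1:
        return values
    kernel = np.ones(window)
    num = np.convolve(values, kernel, mode="same")
    den = np.convolve(np.ones_like(values), kernel, mode="same")
    return num / den


def speeds(traj: Trajectory, window: int = 5) -> SpeedSeries:
    """Forward-difference speed series, smoothed over *window* samples.

    *window* must be odd (so the average is centred) and at least 1.
    """
    if len(traj) < 2:
        raise ValueError("trajectory needs at least 2 points")
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be odd and >= 1")
    dt_s = np.diff(traj.t_ms) / 1000.0
    if np.any(dt_s <= 0):
        raise ValueError("timestamps must be strictly increasing")
    disp = np.hypot(np.diff(traj.x_um), np.diff(traj.y_um))
    raw = disp / dt_s
    mid_t = (traj.t_ms[:-1] + traj.t_ms[1:]) / 2.0
    return SpeedSeries(
        t_ms=mid_t,
        speed_um_s=_moving_average(raw, window),
        raw_um_s=raw,
        dt_s=dt_s,
        window=window,
    )


def summarize(s: SpeedSeries) -> SpeedSummary:
    """Duration-weighted distribution summary plus total distance.

    Total distance is the sum of raw displacements (speed x interval
    duration), i.e. exactly the trajectory arc length.
    """
    if len(s) == 0:
        raise ValueError("empty speed series")
    w = s.dt_s / s.dt_s.sum()
    order = np.argsort(s.speed_um_s)
    cw = np.cumsum(w[order])
    sorted_v = s.speed_um_s[order]

    def quantile(q: float) -> float:
        return float(sorted_v[np.searchsorted(cw, q, side="left").clip(0, len(sorted_v) - 1)])

    return SpeedSummary(
        mean_um_s=float(np.sum(w * s.speed_um_s)),
        max_um_s=float(s.speed_um_s.max()),
        median_um_s=quantile(0.5),
        q1_um_s=quantile(0.25),
        q3_um_s=quantile(0.75),
        # distance from the raw displacements: smoothing redistributes speed
        # across intervals and does not conserve the sum at the edges
        total_distance_um=float(np.sum(s.raw_um_s * s.dt_s)),
        duration_s=float(s.dt_s.sum()),
    )


def body_lengths_per_second(speed_um_s: float, body_length_um: float) -> float:
    """Normalise a speed by organism body length (cross-species metric)."""
    if body_length_um <= 0:
        raise ValueError("body length must be positive")
    return speed_um_s / body_length_um


def segment_motion(
    s: SpeedSeries,
    v_on: float,
    v_off: float,
    min_dwell_ms: float = 0.0,
) -> List[StateSegment]:
    """Hysteresis segmentation into moving / stationary bouts.

    The series enters "moving" when speed exceeds *v_on* and returns to
    "stationary" when it falls below *v_off* (``v_off <= v_on``).
    Segments shorter than *min_dwell_ms* are merged into a neighbour,
    the longer neighbour winning (ties: the earlier one), until every
    segment satisfies the minimum dwell.
    """
    if v_off > v_on:
        raise ValueError("hysteresis requires v_off <= v_on")
    if len(s) == 0:
        raise ValueError("empty speed series")
    v = s.speed_um_s
    states = np.empty(len(v), dtype=bool)  # True = moving
    moving = bool(v[0] > v_on)
    for i, sp in enumerate(v):
        if moving and sp < v_off:
            moving = False
        elif not moving and sp > v_on:
            moving = True
        states[i] = moving

    # sample i covers [t_ms[i] - dt/2, t_ms[i] + dt/2) around its midpoint
    starts = s.t_ms - s.dt_s * 500.0
    ends = s.t_ms + s.dt_s * 500.0
    segments: List[StateSegment] = []
    run_start = 0
    for i in range(1, len(states) + 1):
        if i == len(states) or states[i] != states[run_start]:
            segments.append(
                StateSegment(
                    state="moving" if states[run_start] else "stationary",
                    t_start_ms=float(starts[run_start]),
                    t_end_ms=float(ends[i - 1]),
                )
            )
            run_start = i
    return _merge_short(segments, min_dwell_ms)


def _coalesce(segments: List[StateSegment]) -> List[StateSegment]:
    out: List[StateSegment] = []
    for seg in segments:
        if out and out[-1].state == seg.state:
            out[-1] = StateSegment(seg.state, out[-1].t_start_ms, seg.t_end_ms)
        else:
            out.append(seg)
    return out


def _merge_short(segments: List[StateSegment], min_dwell_ms: float) -> List[StateSegment]:
    segs = _coalesce(list(segments))
    while len(segs) > 1:
        short = [
            (seg.duration_ms, i) for i, seg in enumerate(segs) if seg.duration_ms < min_dwell_ms
        ]
        if not short:
            break
        _, i = min(short)  # shortest first; ties -> earliest
        left = segs[i - 1] if i > 0 else None
        right = segs[i + 1] if i + 1 < len(segs) else None
        if left is not None and (right is None or left.duration_ms >= right.duration_ms):
            winner = left.state
        else:
            winner = right.state
        segs[i] = StateSegment(winner, segs[i].t_start_ms, segs[i].t_end_ms)
        segs = _coalesce(segs)
    return segs
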