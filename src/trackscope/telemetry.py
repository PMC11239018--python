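"""The 50 ms telemetry record, its CSV dialect, and path reconstruction.

During a track the logger records, every 50 ms, the organism's position
relative to the centre of the video frame (signed pixels) and the
platform's position relative to its starting point (micrometres).  The
absolute organism path is the sum of the two displacement cumulants,
per axis:

    P(x_o, y_o) = P(dx_o/f + dx_p,  dy_o/f + dy_p)

where the in-frame cumulant adds per-sample pixel deltas scaled by the
pixel size, and the platform cumulant adds up all platform
displacements over the track.  Keeping the in-frame cumulant in
micrometres (scaling each delta as it is added) is algebraically
identical to scaling the summed pixel displacement for a constant pixel
scale, and stays well-defined across tracker re-initialisations.

CSV dialect (exact): header ``t_ms,x_frame_px,y_frame_px,x_stage_um,
y_stage_um``; t_ms and pixels as integers; micrometres with three
decimal places, '.' separator.  ``read_csv(write_csv(x)) == x``
bit-exactly for values representable in that dialect.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from typing import Iterable, List, Sequence

import numpy as np

__all__ = [
    "TrackRecord",
    "Trajectory",
    "DialectError",
    "CSV_HEADER",
    "update_frame_displacement",
    "update_platform_displacement",
    "reconstruct",
    "write_csv",
    "read_csv",
]

CSV_HEADER = "t_ms,x_frame_px,y_frame_px,x_stage_um,y_stage_um"


class DialectError(ValueError):
    """Telemetry file does not conform to the CSV dialect."""


@dataclass(frozen=True)
class TrackRecord:
    """One 50 ms telemetry sample."""

    t_ms: int
    x_frame_px: int
    y_frame_px: int
    x_stage_um: float
    y_stage_um: float


@dataclass(frozen=True)
class Trajectory:
    """Reconstructed absolute organism path, origin at the first sample."""

    t_ms: np.ndarray
    x_um: np.ndarray
    y_um: np.ndarray
    pixel_scale_um: float

    def __len__(self) -> int:
        return len(self.t_ms)

    def path_length_um(self) -> float:
        """Total arc length: sum of consecutive Euclidean displacements."""
        return float(np.hypot(np.diff(self.x_um), np.diff(self.y_um)).sum())


def update_frame_displacement(cum_um: float, px_now: float, px_prev: float, pixel_scale_um: float) -> float:
    """Advance the in-frame displacement cumulant by one sample, in um."""
    return cum_um + (px_now - px_prev) * pixel_scale_um


def update_platform_displacement(cum_um: float, axis_velocity_um_s: float, dt_ms: float = 50.0) -> float:
    """Advance the platform cumulant from axis velocity over one sample.

    This is the velocity-integration form the original firmware used
    (velocity x 50 ms per sample); in simulation the stage's true
    position is also logged so the quantisation error of this form is
    measurable against it.
    """
    return cum_um + axis_velocity_um_s * (dt_ms / 1000.0)


def reconstruct(records: Sequence[TrackRecord], pixel_scale_um: float) -> Trajectory:
    """Combine frame and platform displacements into the absolute path.

    Per axis: position = in-frame cumulant + platform cumulant, with the
    first sample mapped to (0, 0) by construction.
    """
    if len(records) < 2:
        raise ValueError("need at least 2 records to reconstruct a trajectory")
    t = np.array([r.t_ms for r in records], dtype=float)
    if np.any(np.diff(t) <= 0):
        raise ValueError("timestamps must be strictly increasing")
    fx = np.array([r.x_frame_px for r in records], dtype=float)
    fy = np.array([r.y_frame_px for r in records], dtype=float)
    sx = np.array([r.x_stage_um for r in records], dtype=float)
    sy = np.array([r.y_stage_um for r in records], dtype=float)
    x = (fx - fx[0]) * pixel_scale_um + (sx - sx[0])
    y = (fy - fy[0]) * pixel_scale_um + (sy - sy[0])
    return Trajectory(t_ms=t, x_um=x, y_um=y, pixel_scale_um=pixel_scale_um)


def _format_um(v: float) -> str:
    return f"{v:.3f}"


def write_csv(records: Iterable[TrackRecord], path) -> None:
    """Write telemetry in the exact dialect (header above, LF newlines)."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(CSV_HEADER.split(","))
        for r in records:
            writer.writerow(
                [r.t_ms, r.x_frame_px, r.y_frame_px, _format_um(r.x_stage_um), _format_um(r.y_stage_um)]
            )


def read_csv(path) -> List[TrackRecord]:
    """Read telemetry, enforcing the dialect strictly.

    Raises :class:`DialectError` on a missing or permuted header and on
    any non-numeric cell (the 1-based data-row index is named).
    """
    records: List[TrackRecord] = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise DialectError("empty file: missing header") from None
        if ",".join(header) != CSV_HEADER:
            raise DialectError(f"bad header {','.join(header)!r}; expected {CSV_HEADER!r}")
        for i, row in enumerate(reader, start=1):
            if len(row) != 5:
                raise DialectError(f"row {i}: expected 5 cells, got {len(row)}")
            try:
                records.append(
                    TrackRecord(
                        t_ms=int(row[0]),
                        x_frame_px=int(row[1]),
                        y_frame_px=int(row[2]),
                        x_stage_um=float(row[3]),
                        y_stage_um=float(row[4]),
                    )
                )
            except ValueError:
                raise DialectError(f"row {i}: non-numeric cell in {row!r}") from None
    return records
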