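"""USAF 1951 resolution arithmetic and optical calibration helpers.

A USAF 1951 target indexes bar triplets by (group, element); the spatial
frequency of element *E* in group *G* is ``2^(G + (E-1)/6)`` line pairs
per millimetre, and the centre-to-centre line distance is its reciprocal
in micrometres, ``1000 / lp_per_mm``.  Reading the finest resolved
element off a captured image therefore gives the optical resolution, and
dividing that known physical period by the bar period measured in pixels
gives the pixel scale in um/px.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "UsafIndex",
    "LineProfile",
    "CalibrationError",
    "usaf_lp_per_mm",
    "usaf_resolution_um",
    "estimate_pixel_scale",
    "brightness_percent",
    "sample_profile",
]

#: Minimum peak-to-trough contrast (gray levels) for a usable profile.
MIN_CONTRAST = 10.0


class CalibrationError(ValueError):
    """Profile unusable for pixel-scale estimation."""


@dataclass(frozen=True)
class UsafIndex:
    """(group, element) address of a USAF 1951 resolution element."""

    group: int
    element: int

    def __post_init__(self) -> None:
        if not 1 <= self.element <= 6:
            raise ValueError(f"element must be in 1..6, got {self.element}")


@dataclass(frozen=True)
class LineProfile:
    """Intensity samples along a line across a bar target.

    ``spacing_um`` is the physical distance between consecutive samples
    when known, ``None`` when the pixel scale is the unknown being
    estimated.
    """

    intensity: tuple
    spacing_um: Optional[float] = None

    def __post_init__(self) -> None:
        if len(self.intensity) < 3:
            raise ValueError("profile needs at least 3 samples")

    @classmethod
    def from_array(cls, values: Sequence[float], spacing_um: Optional[float] = None):
        return cls(intensity=tuple(float(v) for v in values), spacing_um=spacing_um)


def usaf_lp_per_mm(idx: UsafIndex) -> float:
    """Spatial frequency of a USAF element, line pairs per millimetre."""
    return 2.0 ** (idx.group + (idx.element - 1) / 6.0)


def usaf_resolution_um(idx: UsafIndex) -> float:
    """Centre-to-centre line distance of a USAF element, micrometres."""
    return 1000.0 / usaf_lp_per_mm(idx)


def brightness_percent(frame) -> float:
    """Mean grayscale brightness of a frame as a percentage of full scale."""
    arr = np.asarray(frame, dtype=float)
    if arr.size == 0:
        raise ValueError("empty frame")
    return float(arr.mean() / 255.0 * 100.0)


def _peak_positions(values: np.ndarray) -> np.ndarray:
    """Centres of above-mean runs after mean-level thresholding.

    Mean-level crossing is preferred over derivative zero-crossings: it
    is robust to mild noise on the short profiles a user samples by
    hand, and run centres are sub-sample accurate for symmetric bars.
    """
    above = values > values.mean()
    # run boundaries of the boolean mask
    edges = np.flatnonzero(np.diff(above.astype(np.int8)))
    starts = list(edges[~above[edges]] + 1)  # False->True transitions
    ends = list(edges[above[edges]] + 1)  # True->False transitions
    if above[0]:
        starts.insert(0, 0)
    if above[-1]:
        ends.append(len(values))
    return np.array([(s + e - 1) / 2.0 for s, e in zip(starts, ends)])


def estimate_pixel_scale(profile: LineProfile, idx: UsafIndex) -> float:
    """Estimate um/px from a bar-target intensity profile.

    The bar period in pixels is the mean spacing of successive bright-bar
    centres after mean-level thresholding; the known physical period of
    the element (its centre-to-centre distance) divided by that pixel
    period is the pixel scale.

    Raises
    ------
    CalibrationError
        ``"low contrast"`` when peak-to-trough span is below
        :data:`MIN_CONTRAST` gray levels; ``"insufficient periods"``
        when fewer than two bar peaks are found.
    """
    values = np.asarray(profile.intensity, dtype=float)
    if values.max() - values.min() < MIN_CONTRAST:
        raise CalibrationError("low contrast: peak-to-trough span below 10 gray levels")
    peaks = _peak_positions(values)
    if len(peaks) < 2:
        raise CalibrationError("insufficient periods: need at least 2 bar peaks")
    period_px = float(np.diff(peaks).mean())
    return usaf_resolution_um(idx) / period_px


def sample_profile(image, start, end, band_px: int = 3) -> LineProfile:
    """Sample an intensity profile along a line, averaging a band.

    The profile is averaged over a ``band_px``-pixel-wide band normal to
    the line (3 px by default), which suppresses single-row noise without
    blurring the bars.  Endpoints are (x, y) pixel coordinates.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim == 3:  # collapse colour to gray
        img = img.mean(axis=2)
    x0, y0 = float(start[0]), float(start[1])
    x1, y1 = float(end[0]), float(end[1])
    length = int(round(np.hypot(x1 - x0, y1 - y0)))
    if length < 2:
        raise ValueError("line endpoints too close")
    t = np.linspace(0.0, 1.0, length + 1)
    xs = x0 + t * (x1 - x0)
    ys = y0 + t * (y1 - y0)
    # unit normal to the line
    nx, ny = -(y1 - y0), (x1 - x0)
    norm = np.hypot(nx, ny)
    nx, ny = nx / norm, ny / norm
    offsets = np.arange(band_px) - (band_px - 1) / 2.0
    acc = np.zeros_like(xs)
    h, w = img.shape
    for o in offsets:
        xi = np.clip(np.round(xs + o * nx).astype(int), 0, w - 1)
        yi = np.clip(np.round(ys + o * ny).astype(int), 0, h - 1)
        acc += img[yi, xi]
    return LineProfile.from_array(acc / band_px)
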