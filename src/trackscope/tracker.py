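"""Pluggable single-object tracker with a native segmentation backend.

The control loop only ever sees a :class:`BoundingBox`, so any tracker
that can initialise on a user-chosen ROI and return an updated box per
frame can drive the stage.  The instrument uses OpenCV's CSRT
(a discriminative-correlation-filter tracker) in that role; here CSRT is
an optional backend behind the same contract, and the default *native*
backend segments the organism against a background estimate — fully
adequate for the synthetic bright/dark-field scenes the simulator
renders, and dependency-free.

Native backend algorithm
------------------------
The background gray level is the median of the frame border pixels,
pooled over the first five frames; the noise level is a robust (MAD)
estimate from the same border.  Foreground is ``|pixel - background| >
max(10, 3 * noise)``; tiny components (< 5 px) are discarded as noise
specks.  Among the remaining connected components the one whose centroid
is nearest the previous box centre is taken (ties: larger area, then
smaller x, then smaller y).  Confidence is the component area over the
area at initialisation, capped at 1; track loss is declared by the
caller via :func:`is_lost` when confidence drops below a threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Tuple

import numpy as np
from scipy import ndimage

__all__ = [
    "BoundingBox",
    "TrackerState",
    "EmptyRoiError",
    "init_tracker",
    "update_tracker",
    "is_lost",
    "available_backends",
]

#: Components smaller than this many pixels are ignored as noise specks.
MIN_COMPONENT_PX = 5

#: Frames over which the border-median background estimate is pooled.
BACKGROUND_FRAMES = 5

#: Default confidence threshold below which a track counts as lost.
DEFAULT_LOSS_THRESHOLD = 0.2


class EmptyRoiError(ValueError):
    """The initial ROI contains no foreground component."""


@dataclass(frozen=True)
class BoundingBox:
    """Axis-aligned box in pixel coordinates, origin at frame top-left."""

    x: float
    y: float
    w: float
    h: float

    def __post_init__(self) -> None:
        if self.w <= 0 or self.h <= 0:
            raise ValueError("bounding box must have positive width and height")

    @property
    def center(self) -> Tuple[float, float]:
        return (self.x + self.w / 2.0, self.y + self.h / 2.0)

    def within(self, frame_w: int, frame_h: int) -> bool:
        return 0 <= self.x and 0 <= self.y and self.x + self.w <= frame_w and self.y + self.h <= frame_h

    def intersects(self, frame_w: int, frame_h: int) -> bool:
        return self.x < frame_w and self.y < frame_h and self.x + self.w > 0 and self.y + self.h > 0


@dataclass
class TrackerState:
    """Tracker bookkeeping; reference data is backend-private."""

    backend_id: str
    last_box: BoundingBox
    confidence: float
    initial_area: float
    background: float = 0.0
    threshold: float = 10.0
    frames_seen: int = 0
    border_medians: List[float] = field(default_factory=list)
    handle: object = None  # opaque external-backend handle (e.g. cv2 tracker)


# ---------------------------------------------------------------------------
# native backend internals


def _border_pixels(frame: np.ndarray) -> np.ndarray:
    return np.concatenate([frame[0, :], frame[-1, :], frame[1:-1, 0], frame[1:-1, -1]]).astype(float)


def _noise_mad(border: np.ndarray) -> float:
    med = np.median(border)
    return 1.4826 * float(np.median(np.abs(border - med)))


def _foreground_components(frame: np.ndarray, background: float, threshold: float):
    """Label foreground and return (area, centroid, bbox) per component."""
    # two native-dtype comparisons instead of |frame - bg| in a wider dtype
    if frame.dtype == np.uint8:
        lo = np.uint8(max(0.0, np.floor(background - threshold)))
        hi = np.uint8(min(255.0, np.ceil(background + threshold)))
        mask = (frame < lo) | (frame > hi)
    else:
        mask = (frame < background - threshold) | (frame > background + threshold)
    labels, n = ndimage.label(mask)
    if n == 0:
        return []
    # per-component stats from the sparse foreground coordinates: far
    # cheaper than find_objects on the full frame when noise specks
    # produce many tiny labels
    ys, xs = np.nonzero(mask)
    labs = labels[ys, xs]
    areas = np.bincount(labs, minlength=n + 1)
    keep = np.flatnonzero(areas >= MIN_COMPONENT_PX)
    keep = keep[keep > 0]
    out = []
    for lab in keep:
        sel = labs == lab
        cys, cxs = ys[sel], xs[sel]
        x0, x1 = cxs.min(), cxs.max()
        y0, y1 = cys.min(), cys.max()
        box = BoundingBox(x=float(x0), y=float(y0), w=float(x1 - x0 + 1), h=float(y1 - y0 + 1))
        out.append((float(areas[lab]), (float(cxs.mean()), float(cys.mean())), box))
    return out


def _nearest_component(components, center: Tuple[float, float]):
    """Nearest centroid; ties broken by larger area, then smaller x, y."""
    cx, cy = center

    def key(comp):
        area, (x, y), _ = comp
        d2 = (x - cx) ** 2 + (y - cy) ** 2
        return (round(d2, 6), -area, x, y)

    return min(components, key=key)


# ---------------------------------------------------------------------------
# public contract


def available_backends() -> Tuple[str, ...]:
    """Backends usable in this environment."""
    try:  # pragma: no cover - depends on optional install
        import cv2  # noqa: F401

        return ("native", "csrt")
    except ImportError:
        return ("native",)


def init_tracker(frame, roi: BoundingBox, backend_id: str = "native") -> TrackerState:
    """Initialise a tracker on the user-selected ROI.

    The ROI must lie fully inside the frame and, for the native backend,
    contain at least one foreground component.
    """
    frame = np.asarray(frame)
    h, w = frame.shape[:2]
    if not roi.within(w, h):
        raise ValueError("ROI must lie fully within the frame")
    if backend_id == "csrt":
        return _init_csrt(frame, roi)
    if backend_id != "native":
        raise ValueError(f"unknown tracker backend {backend_id!r}")

    border = _border_pixels(frame)
    background = float(np.median(border))
    threshold = max(10.0, 3.0 * _noise_mad(border))
    ys = slice(int(roi.y), int(roi.y + roi.h))
    xs = slice(int(roi.x), int(roi.x + roi.w))
    patch = frame[ys, xs]
    comps = _foreground_components(patch, background, threshold)
    if not comps:
        raise EmptyRoiError("empty ROI: no foreground component inside the selection")
    initial_area = max(c[0] for c in comps)
    return TrackerState(
        backend_id="native",
        last_box=roi,
        confidence=1.0,
        initial_area=initial_area,
        background=background,
        threshold=threshold,
        frames_seen=1,
        border_medians=[background],
    )


def update_tracker(state: TrackerState, frame) -> Tuple[TrackerState, BoundingBox]:
    """Advance the tracker one frame; returns (state, bounding box).

    Never raises on track loss: when no foreground component remains the
    confidence falls to 0 and the previous box is returned, letting the
    caller decide via :func:`is_lost`.
    """
    frame = np.asarray(frame)
    if state.backend_id == "csrt":
        return _update_csrt(state, frame)

    # pool the background estimate over the first few frames
    if state.frames_seen < BACKGROUND_FRAMES:
        state.border_medians.append(float(np.median(_border_pixels(frame))))
        state.background = float(np.median(state.border_medians))
    state.frames_seen += 1

    comps = _foreground_components(frame, state.background, state.threshold)
    if not comps:
        state.confidence = 0.0
        return state, state.last_box
    area, _, box = _nearest_component(comps, state.last_box.center)
    state.last_box = box
    state.confidence = min(1.0, area / state.initial_area)
    return state, box


def is_lost(state: TrackerState, threshold: float = DEFAULT_LOSS_THRESHOLD) -> bool:
    """True when confidence has fallen strictly below *threshold*."""
    return state.confidence < threshold


# ---------------------------------------------------------------------------
# optional CSRT backend (requires opencv-python from the `imaging` extra)


def _init_csrt(frame: np.ndarray, roi: BoundingBox) -> TrackerState:
    try:
        import cv2
    except ImportError as exc:  # pragma: no cover
        raise ImportError(
            "the 'csrt' backend needs opencv-python (install the 'imaging' extra)"
        ) from exc
    tracker = cv2.TrackerCSRT_create()  # pragma: no cover
    bgr = cv2.cvtColor(frame.astype(np.uint8), cv2.COLOR_GRAY2BGR)  # pragma: no cover
    tracker.init(bgr, (int(roi.x), int(roi.y), int(roi.w), int(roi.h)))  # pragma: no cover
    return TrackerState(  # pragma: no cover
        backend_id="csrt",
        last_box=roi,
        confidence=1.0,
        initial_area=roi.w * roi.h,
        handle=tracker,
    )


def _update_csrt(state: TrackerState, frame: np.ndarray):  # pragma: no cover
    import cv2

    bgr = cv2.cvtColor(frame.astype(np.uint8), cv2.COLOR_GRAY2BGR)
    ok, (x, y, w, h) = state.handle.update(bgr)
    if ok and w > 0 and h > 0:
        state.last_box = BoundingBox(float(x), float(y), float(w), float(h))
        state.confidence = 1.0
    else:
        state.confidence = 0.0
    return state, state.last_box
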