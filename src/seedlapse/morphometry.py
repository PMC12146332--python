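"""Measurement core: crop, binarize, count white pixels, build growth series.

The germination proxy is simple pixel morphometry: crop each annotated seed,
threshold the grayscale crop at a fixed intensity (default 120, with ties
mapped to background), and count foreground pixels.  Repeating this per time
point yields a growth series of (hours, white-pixel count) samples for
downstream curve fitting.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from seedlapse.voc_io import AnnotatedFrame, BoundingBox

DEFAULT_THRESHOLD = 120

#: ITU-R BT.601 luma weights for RGB -> grayscale reduction.
_LUMA = np.array([0.299, 0.587, 0.114])


@dataclass(frozen=True)
class GrowthSeries:
    """Per-dish white-pixel counts over time; x = hours, y = pixel count."""

    dish_id: str
    times: tuple[float, ...]
    counts: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.times) != len(self.counts):
            raise ValueError("times and counts must have equal length")
        t = np.asarray(self.times, dtype=float)
        if len(t) > 1 and not np.all(np.diff(t) > 0):
            raise ValueError("times must be strictly increasing")
        if any(c < 0 for c in self.counts):
            raise ValueError("counts must be non-negative")

    def __len__(self) -> int:
        return len(self.times)

    @property
    def x(self) -> np.ndarray:
        return np.asarray(self.times, dtype=float)

    @property
    def y(self) -> np.ndarray:
        return np.asarray(self.counts, dtype=float)


def crop(image: np.ndarray, box: BoundingBox) -> np.ndarray:
    """Extract the box region (clipped to image bounds) from an image."""
    h, w = image.shape[:2]
    clipped = box.clip(h, w)
    return image[clipped.ymin : clipped.ymax, clipped.xmin : clipped.xmax, ...]


def to_gray(image: np.ndarray) -> np.ndarray:
    """Reduce to a single channel.

    3-channel inputs use BT.601 luma, rounded half up; single-channel inputs
    pass through bit-identically.
    """
    if image.ndim == 2:
        return image
    if image.ndim == 3 and image.shape[2] == 1:
        return image[:, :, 0]
    if image.ndim == 3 and image.shape[2] == 3:
        luma = image.astype(np.float64) @ _LUMA
        return np.floor(luma + 0.5).astype(np.uint8)
    raise ValueError(f"expected 1 or 3 channels, got shape {image.shape}")


def binarize(gray: np.ndarray, threshold: int = DEFAULT_THRESHOLD) -> np.ndarray:
    """Threshold a grayscale image: 1 where intensity > threshold, else 0.

    A pixel exactly at the threshold maps to 0 (background).
    """
    if not 0 <= threshold <= 255:
        raise ValueError(f"threshold must lie in [0, 255], got {threshold}")
    if gray.ndim != 2:
        raise ValueError(f"binarize expects a 2D grayscale array, got ndim={gray.ndim}")
    return (gray > threshold).astype(np.uint8)


def count_white(binary: np.ndarray) -> int:
    """Number of foreground (value 1) pixels of a binary image."""
    arr = np.asarray(binary)
    if not np.isin(arr, (0, 1)).all():
        raise ValueError("binary image may only contain 0 and 1")
    return int(arr.sum())


def measure_box(image: np.ndarray, box: BoundingBox, threshold: int = DEFAULT_THRESHOLD) -> int:
    """White-pixel count of one annotated seed crop."""
    return count_white(binarize(to_gray(crop(image, box)), threshold))


def _nearest_box(boxes: Sequence[BoundingBox], ref: BoundingBox) -> BoundingBox:
    """Box whose center is nearest to ``ref``'s; ambiguity is an error."""
    rx, ry = ref.center
    dists = [np.hypot(b.center[0] - rx, b.center[1] - ry) for b in boxes]
    order = np.argsort(dists)
    if len(order) > 1 and abs(dists[order[0]] - dists[order[1]]) < 1e-9:
        raise ValueError(f"ambiguous track: two boxes equally near center ({rx:.1f}, {ry:.1f})")
    return boxes[order[0]]


def assemble_series(
    frames: Sequence[tuple[AnnotatedFrame, np.ndarray]],
    dish_id: str,
    track: int | Callable[[AnnotatedFrame], BoundingBox] = 0,
    start_h: float = 24.0,
    step_h: float = 1.0,
    end_h: float = 48.0,
    threshold: int = DEFAULT_THRESHOLD,
) -> GrowthSeries:
    """Build a growth series for one tracked seed across a frame stack.

    ``track`` selects the seed: an integer indexes the boxes of the first
    sampled frame, after which the tracked box is followed by
    nearest-center matching; a callable receives each frame and must return
    the box to measure (manual override).

    Requested time points run ``start_h, start_h + step_h, ..., end_h``;
    each is served by the nearest frame, which must lie within half the
    acquisition interval.
    """
    if not frames:
        raise ValueError("empty frame list")
    if step_h <= 0 or end_h < start_h:
        raise ValueError("need step_h > 0 and end_h >= start_h")

    ordered = sorted(frames, key=lambda fr: fr[0].time_h)
    frame_times = np.array([fr[0].time_h for fr in ordered])
    interval = float(np.median(np.diff(frame_times))) if len(frame_times) > 1 else float("inf")

    targets = np.arange(start_h, end_h + step_h / 2.0, step_h)
    picks: list[tuple[float, AnnotatedFrame, np.ndarray]] = []
    missing: list[float] = []
    for target in targets:
        idx = int(np.argmin(np.abs(frame_times - target)))
        if abs(frame_times[idx] - target) > interval / 2.0 + 1e-9:
            missing.append(float(target))
            continue
        frame, image = ordered[idx]
        picks.append((float(target), frame, image))
    if missing:
        raise ValueError(f"no frame within half the acquisition interval of hours: {missing}")

    counts: list[int] = []
    ref: BoundingBox | None = None
    for target, frame, image in picks:
        if callable(track):
            box = track(frame)
        elif ref is None:
            if not frame.boxes:
                raise ValueError(f"frame {frame.image_id} has no boxes to track")
            box = frame.boxes[track]
        else:
            if not frame.boxes:
                raise ValueError(f"frame {frame.image_id} has no boxes to track")
            box = _nearest_box(frame.boxes, ref)
        ref = box
        counts.append(measure_box(image, box, threshold))

    return GrowthSeries(dish_id=dish_id, times=tuple(t for t, _, _ in picks), counts=tuple(counts))
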