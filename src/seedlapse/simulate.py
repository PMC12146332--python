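"""Synthetic germination time-lapse generator with analytic ground truth.

Scenes emulate a dark-cloth / Petri-dish imaging rig: a near-black
background, an optional dim dish ring, and bright elliptical seed bodies
whose radicles elongate over time following a configurable growth law.
Intensities are chosen so that a fixed binarization threshold of 120
separates foreground perfectly (background 15 and ring 60 fall below it,
seed bodies and radicles at 200 fall above), which turns every rendered
frame into an exact oracle for the pixel-counting pipeline.

The radicle is drawn as a flat-ended constant-width stroke along a straight
ray from the ellipse boundary, so its rasterized area approximates
``width * length`` and the planted growth law is analytically recoverable
from the measured foreground areas.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from seedlapse.augment import NoiseConfig, sp_noise
from seedlapse.voc_io import AnnotatedFrame, BoundingBox

LABEL_GERMINATED = "germinated"
LABEL_UNGERMINATED = "ungerminated"


@dataclass(frozen=True)
class CubicGrowth:
    """Radicle length ``c3*t^3 + c2*t^2 + c1*t`` pixels, t hours past onset."""

    c3: float
    c2: float
    c1: float

    def length(self, tau: float) -> float:
        if tau <= 0:
            return 0.0
        return max(0.0, self.c3 * tau**3 + self.c2 * tau**2 + self.c1 * tau)


@dataclass(frozen=True)
class LogisticGrowth:
    """Radicle length ``cap / (1 + exp(-rate*(t - t_mid)))`` pixels.

    The small pre-onset plateau is subtracted so length(0) == 0.
    """

    cap: float
    rate: float
    t_mid: float

    def _raw(self, tau: float) -> float:
        return self.cap / (1.0 + math.exp(-self.rate * (tau - self.t_mid)))

    def length(self, tau: float) -> float:
        if tau <= 0:
            return 0.0
        return max(0.0, self._raw(tau) - self._raw(0.0))


@dataclass(frozen=True)
class SeedSpec:
    """One seed: an ellipse body plus a straight radicle stroke."""

    center: tuple[float, float]  # (x, y) pixels
    axes: tuple[float, float]  # semi-axes (a, b) > 0
    growth: CubicGrowth | LogisticGrowth
    t0: float = 24.0  # germination onset, hours
    intensity: int = 200
    sprout_width: float = 3.0
    direction: float = 0.0  # radians, 0 points along +x
    shrink_rate: float = 0.0  # fractional axis shrinkage per hour after t0

    def __post_init__(self) -> None:
        a, b = self.axes
        if a <= 0 or b <= 0:
            raise ValueError(f"ellipse semi-axes must be positive, got {self.axes}")
        if self.sprout_width <= 0:
            raise ValueError(f"sprout width must be positive, got {self.sprout_width}")
        if self.shrink_rate < 0:
            raise ValueError(f"shrink rate must be non-negative, got {self.shrink_rate}")

    def scale(self, t: float) -> float:
        """Body scale factor at time t (linear shrink after onset)."""
        if self.shrink_rate == 0.0 or t <= self.t0:
            return 1.0
        return max(0.0, 1.0 - self.shrink_rate * (t - self.t0))

    def sprout_length(self, t: float) -> float:
        return self.growth.length(t - self.t0)


@dataclass(frozen=True)
class RingSpec:
    """Dim Petri-dish rim: an annulus below the binarization threshold."""

    center: tuple[float, float]
    radius: float
    width: float = 4.0
    intensity: int = 60


@dataclass(frozen=True)
class SceneSpec:
    shape: tuple[int, int] = (256, 256)  # (H, W)
    interval_h: float = 0.5
    duration_h: float = 48.0
    seeds: tuple[SeedSpec, ...] = ()
    background: int = 15
    ring: RingSpec | None = None
    noise: NoiseConfig | None = None
    seed: int = 0
    visible_len: float = 2.0  # radicle length (px) at which a seed counts as germinated

    def __post_init__(self) -> None:
        if self.duration_h <= 0 or self.interval_h <= 0:
            raise ValueError("duration_h and interval_h must be positive")
        h, w = self.shape
        for s in self.seeds:
            cx, cy = s.center
            a, b = s.axes
            if not (a <= cx <= w - 1 - a and b <= cy <= h - 1 - b):
                raise ValueError(f"seed at {s.center} with axes {s.axes} does not fit in a {h}x{w} image")

    @property
    def n_frames(self) -> int:
        return int(math.floor(self.duration_h / self.interval_h + 1e-9)) + 1

    def frame_times(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.interval_h

    def frame_id(self, index: int) -> str:
        return f"frame_{index:04d}"


def _ellipse_boundary_radius(a: float, b: float, direction: float) -> float:
    """Distance from the ellipse center to its boundary along ``direction``."""
    c, s = math.cos(direction), math.sin(direction)
    return a * b / math.hypot(b * c, a * s)


def _seed_mask(shape: tuple[int, int], seed: SeedSpec, t: float) -> np.ndarray:
    """Exact boolean foreground mask of one seed (body + radicle) at time t."""
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    cx, cy = seed.center
    a, b = seed.axes
    k = seed.scale(t)
    if k <= 0:
        body = np.zeros(shape, dtype=bool)
    else:
        body = ((xx - cx) / (a * k)) ** 2 + ((yy - cy) / (b * k)) ** 2 <= 1.0

    length = seed.sprout_length(t)
    if length <= 0:
        return body

    ux, uy = math.cos(seed.direction), math.sin(seed.direction)
    r0 = _ellipse_boundary_radius(a * max(k, 1e-9), b * max(k, 1e-9), seed.direction)
    px, py = cx + r0 * ux, cy + r0 * uy
    # Flat-ended stroke, half-open on both extents so an axis-aligned stroke
    # of integer width w covers exactly w pixel rows (area ~ width * length).
    axial = (xx - px) * ux + (yy - py) * uy
    lateral = -(xx - px) * uy + (yy - py) * ux
    half_w = seed.sprout_width / 2.0
    stroke = (axial >= 0) & (axial < length) & (lateral >= -half_w) & (lateral < half_w)
    return body | stroke


def _tight_box(mask: np.ndarray, label: str) -> BoundingBox:
    rows = np.flatnonzero(mask.any(axis=1))
    cols = np.flatnonzero(mask.any(axis=0))
    return BoundingBox(
        xmin=int(cols[0]),
        ymin=int(rows[0]),
        xmax=int(cols[-1]) + 1,
        ymax=int(rows[-1]) + 1,
        label=label,
    )


def frame_truth(spec: SceneSpec, t: float) -> list[dict]:
    """Per-seed ground truth at time t: mask area, label and tight box."""
    records = []
    for i, seed in enumerate(spec.seeds):
        mask = _seed_mask(spec.shape, seed, t)
        germinated = seed.sprout_length(t) > spec.visible_len
        label = LABEL_GERMINATED if germinated else LABEL_UNGERMINATED
        records.append(
            {
                "seed_id": i,
                "true_area": int(mask.sum()),
                "label": label,
                "box": _tight_box(mask, label) if mask.any() else None,
                "mask": mask,
            }
        )
    return records


def render_frame(
    spec: SceneSpec,
    t: float,
    frame_index: int = 0,
) -> tuple[np.ndarray, AnnotatedFrame, np.ndarray]:
    """Render one frame.

    Returns ``(image, annotations, true_mask)`` where ``true_mask`` is the
    exact boolean foreground mask before any noise is applied.  Each seed
    contributes one tight bounding box labeled germinated once its radicle
    exceeds the scene's visibility threshold.
    """
    if not 0 <= t <= spec.duration_h + 1e-9:
        raise ValueError(f"t={t} outside [0, {spec.duration_h}]")

    h, w = spec.shape
    image = np.full(spec.shape, spec.background, dtype=np.uint8)

    if spec.ring is not None:
        yy, xx = np.mgrid[0:h, 0:w]
        rcx, rcy = spec.ring.center
        dist = np.hypot(xx - rcx, yy - rcy)
        annulus = np.abs(dist - spec.ring.radius) <= spec.ring.width / 2.0
        image[annulus] = spec.ring.intensity

    true_mask = np.zeros(spec.shape, dtype=bool)
    boxes: list[BoundingBox] = []
    for rec in frame_truth(spec, t):
        mask = rec["mask"]
        true_mask |= mask
        seed = spec.seeds[rec["seed_id"]]
        image[mask] = seed.intensity
        if rec["box"] is not None:
            boxes.append(rec["box"])

    frame = AnnotatedFrame(image_id=spec.frame_id(frame_index), time_h=float(t), boxes=boxes)

    if spec.noise is not None:
        rng = np.random.default_rng(np.random.SeedSequence([spec.noise.seed, frame_index]))
        image = sp_noise(image, spec.noise, rng=rng)

    return image, frame, true_mask


def render_stack(spec: SceneSpec) -> list[tuple[np.ndarray, AnnotatedFrame, int]]:
    """Render the full time lapse.

    Returns one ``(image, annotations, true_area)`` triple per frame, where
    ``true_area`` is the exact foreground pixel count recorded before noise.
    """
    stack = []
    for i, t in enumerate(spec.frame_times()):
        image, frame, mask = render_frame(spec, float(t), frame_index=i)
        stack.append((image, frame, int(mask.sum())))
    return stack


def random_scene(
    n_seeds: int = 4,
    shape: tuple[int, int] = (256, 256),
    rng: np.random.Generator | int | None = None,
    noise: NoiseConfig | None = None,
    duration_h: float = 48.0,
    interval_h: float = 0.5,
    shrink_rate: float = 0.0,
) -> SceneSpec:
    """Draw a plausible random scene: non-overlapping seeds on a grid jitter.

    Growth laws are gentle cubics with onsets in the first day, sized so the
    radicle stays inside the frame over the configured duration.
    """
    if isinstance(rng, (int, np.integer)) or rng is None:
        rng = np.random.default_rng(rng)
    h, w = shape
    cols = max(1, int(math.ceil(math.sqrt(n_seeds))))
    rows = int(math.ceil(n_seeds / cols))
    cell_w, cell_h = w / cols, h / rows
    seeds = []
    for i in range(n_seeds):
        r, c = divmod(i, cols)
        a = rng.uniform(6, 10)
        b = rng.uniform(5, 8)
        cx = (c + 0.5) * cell_w + rng.uniform(-0.08, 0.08) * cell_w
        cy = (r + 0.5) * cell_h + rng.uniform(-0.08, 0.08) * cell_h
        t0 = rng.uniform(12, 24)
        horizon = duration_h - t0
        # Cap the final radicle length to roughly a third of the cell.
        final = rng.uniform(0.2, 0.33) * min(cell_w, cell_h)
        c1 = rng.uniform(0.05, 0.2)
        c3 = max(0.0, (final - c1 * horizon) / horizon**3)
        seeds.append(
            SeedSpec(
                center=(cx, cy),
                axes=(a, b),
                growth=CubicGrowth(c3=c3, c2=0.0, c1=c1),
                t0=t0,
                direction=rng.uniform(0, 2 * math.pi),
                sprout_width=3.0,
                shrink_rate=shrink_rate,
            )
        )
    return SceneSpec(
        shape=shape,
        duration_h=duration_h,
        interval_h=interval_h,
        seeds=tuple(seeds),
        noise=noise,
        seed=int(rng.integers(0, 2**31)),
    )
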