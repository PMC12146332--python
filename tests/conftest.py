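import math

import numpy as np
import pytest

from seedlapse.morphometry import GrowthSeries
from seedlapse.simulate import CubicGrowth, SceneSpec, SeedSpec
from seedlapse.voc_io import AnnotatedFrame, BoundingBox


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_random_frame(rng, n_boxes=None, image_size=(256, 256)):
    """Random annotated frame for round-trip tests."""
    h, w = image_size
    if n_boxes is None:
        n_boxes = int(rng.integers(0, 6))
    boxes = []
    for _ in range(n_boxes):
        xmin = int(rng.integers(0, w - 2))
        ymin = int(rng.integers(0, h - 2))
        xmax = int(rng.integers(xmin + 1, w))
        ymax = int(rng.integers(ymin + 1, h))
        label = "germinated" if rng.random() < 0.5 else "ungerminated"
        boxes.append(BoundingBox(xmin, ymin, xmax, ymax, label))
    return AnnotatedFrame(
        image_id=f"img_{int(rng.integers(0, 10**6)):06d}",
        time_h=float(np.round(rng.uniform(0, 48), 3)),
        boxes=boxes,
    )


def single_seed_scene(
    growth=CubicGrowth(c3=0.002, c2=0.0, c1=0.8),
    t0=20.0,
    shape=(128, 128),
    duration_h=48.0,
    interval_h=0.5,
    direction=0.0,
    sprout_width=4.0,
    shrink_rate=0.0,
    noise=None,
    seed=0,
):
    """One centered seed; the radicle stays inside the frame for the defaults."""
    h, w = shape
    return SceneSpec(
        shape=shape,
        duration_h=duration_h,
        interval_h=interval_h,
        noise=noise,
        seed=seed,
        seeds=(
            SeedSpec(
                center=(w * 0.35, h * 0.5),
                axes=(10.0, 8.0),
                growth=growth,
                t0=t0,
                direction=direction,
                sprout_width=sprout_width,
                shrink_rate=shrink_rate,
            ),
        ),
    )


@pytest.fixture
def cubic_series():
    """Exact samples of a cubic on the hourly grid 24..48."""
    x = np.arange(24.0, 49.0)
    y = 0.05 * x**3 - 2.0 * x**2 + 60.0 * x + 1500.0
    return GrowthSeries("dish", tuple(x), tuple(int(round(v)) for v in y))
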