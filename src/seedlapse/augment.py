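"""Salt-and-pepper (impulse) noise augmentation.

Each pixel is independently replaced with probability ``factor``; a replaced
pixel becomes white (255) with probability ``salt_share``, otherwise black
(0).  For colour images the replacement is drawn per pixel location and
applied to all channels together, which is how impulse noise looks on real
sensors.  Inputs are never modified in place.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class NoiseConfig:
    factor: float = 0.2
    salt_share: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.factor <= 1.0:
            raise ValueError(f"noise factor must lie in [0, 1], got {self.factor}")
        if not 0.0 <= self.salt_share <= 1.0:
            raise ValueError(f"salt_share must lie in [0, 1], got {self.salt_share}")


def sp_noise(
    image: np.ndarray,
    cfg: NoiseConfig,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Return a salt-and-pepper corrupted copy of ``image``.

    Pixels not selected for replacement are bit-identical to the input.
    ``rng`` overrides the generator derived from ``cfg.seed`` (used by the
    simulator to decorrelate frames while staying deterministic).
    """
    if image.ndim not in (2, 3):
        raise ValueError(f"expected a 2D or 3D image, got ndim={image.ndim}")
    if rng is None:
        rng = np.random.default_rng(cfg.seed)

    out = image.copy()
    spatial = image.shape[:2]
    replace = rng.random(spatial) < cfg.factor
    salt = rng.random(spatial) < cfg.salt_share
    if image.ndim == 2:
        out[replace & salt] = 255
        out[replace & ~salt] = 0
    else:
        out[replace & salt, :] = 255
        out[replace & ~salt, :] = 0
    return out
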