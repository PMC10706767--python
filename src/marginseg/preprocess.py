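"""Image pre-processing and training-time augmentation.

The acquisition pipeline keeps only the top half of each B-mode frame
(margin assessment happens near the specimen surface), resizes to a square
network input, and normalizes intensities to [0, 1]. Augmentation applies
a left-right mirror, a small rotation, and gamma correction.
"""

from __future__ import annotations

import warnings

import numpy as np
from skimage import transform

from .image import USImage

__all__ = ["crop_top_half", "resize_and_normalize", "augment"]


def crop_top_half(image: USImage, mask: np.ndarray) -> tuple[USImage, np.ndarray]:
    """Keep rows [0, floor(rows/2)) of image and mask; spacing is unchanged."""
    rows = image.shape[0]
    if rows < 2:
        raise ValueError("image must have at least 2 rows to crop")
    keep = rows // 2
    return image.with_pixels(image.pixels[:keep]), np.asarray(mask)[:keep].copy()


def resize_and_normalize(
    image: USImage,
    mask: np.ndarray,
    target: tuple[int, int] = (128, 128),
) -> tuple[USImage, np.ndarray]:
    """Resize (bilinear image / nearest mask) and min-max normalize to [0, 1].

    Pixel spacing is rescaled by old/new size per axis so physical
    coordinates stay consistent. A constant image cannot be min-max scaled;
    it becomes all zeros with a warning.
    """
    old_r, old_c = image.shape
    new_r, new_c = target
    px = transform.resize(image.pixels, target, order=1, anti_aliasing=True, mode="reflect")
    lo, hi = px.min(), px.max()
    if hi - lo < 1e-12:
        warnings.warn("constant image; normalized to all zeros", stacklevel=2)
        px = np.zeros_like(px)
    else:
        px = (px - lo) / (hi - lo)
    m = transform.resize(np.asarray(mask).astype(float), target, order=0, anti_aliasing=False)
    out = image.with_pixels(
        px,
        row_spacing_mm=image.row_spacing_mm * old_r / new_r,
        col_spacing_mm=image.col_spacing_mm * old_c / new_c,
    )
    return out, (m > 0.5).astype(np.uint8)


def augment(
    image: USImage,
    mask: np.ndarray,
    rng_seed: int | np.random.Generator,
    flip_axis: str = "vertical",
    max_rotation_deg: float = 5.0,
    gamma_range: tuple[float, float] = (0.8, 1.2),
) -> tuple[USImage, np.ndarray]:
    """Random mirror + small rotation + gamma correction, deterministic per seed.

    * mirror about the vertical axis (left-right flip) with probability 1/2
      — mirroring top-bottom would put the transducer surface at the image
      bottom and break the depth semantics the margin metric and the
      depth-weighted loss rely on, so ``flip_axis="horizontal"`` is opt-in;
    * rotation angle uniform in [-5, 5] degrees, bilinear for the image and
      nearest-neighbor (re-binarized) for the mask, corners filled with 0;
    * gamma correction ``P_out = P_in ** gamma`` with gamma uniform in
      [0.8, 1.2], applied to the image only. For inputs in [0, 1] and
      positive gamma the output stays in [0, 1].
    """
    rng = np.random.default_rng(rng_seed) if not isinstance(rng_seed, np.random.Generator) else rng_seed
    px = image.pixels
    m = np.asarray(mask) > 0

    if rng.random() < 0.5:
        if flip_axis == "vertical":
            px, m = px[:, ::-1], m[:, ::-1]
        elif flip_axis == "horizontal":
            px, m = px[::-1, :], m[::-1, :]
        else:
            raise ValueError("flip_axis must be 'vertical' or 'horizontal'")

    angle = rng.uniform(-max_rotation_deg, max_rotation_deg)
    px = transform.rotate(px, angle, order=1, mode="constant", cval=0.0)
    m = transform.rotate(m.astype(float), angle, order=0, mode="constant", cval=0.0) > 0.5

    gamma = rng.uniform(*gamma_range)
    px = np.clip(px, 0.0, 1.0) ** gamma
    return image.with_pixels(px), m.astype(np.uint8)
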