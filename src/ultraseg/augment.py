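"""Geometric augmentation applied identically to an image and its mask.

One random transform per call — horizontal/vertical flips, a rotation +
isotropic scaling about the image centre, and a random crop resized back to
the original frame.  The image is interpolated bilinearly, the mask
nearest-neighbour so it stays strictly binary, and output dims always equal
input dims.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from skimage.transform import AffineTransform, resize, warp

__all__ = ["AugmentSpec", "augment_pair"]


@dataclass(frozen=True)
class AugmentSpec:
    """Defaults are deliberately mild and label-preserving: rotations up to
    +/-25 degrees, both flips at probability 0.5, scaling within 10%, and a
    90% crop."""

    rotation_degrees: tuple[float, float] = (-25.0, 25.0)
    flip_horizontal: float = 0.5
    flip_vertical: float = 0.5
    scale_factor: tuple[float, float] = (0.9, 1.1)
    crop_fraction: float = 0.9
    seed: int = 0

    def __post_init__(self):
        for p, name in ((self.flip_horizontal, "flip_horizontal"),
                        (self.flip_vertical, "flip_vertical")):
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"{name} must be a probability")
        if not (0.0 < self.crop_fraction <= 1.0):
            raise ValueError("crop_fraction must lie in (0, 1]")
        if self.scale_factor[0] <= 0:
            raise ValueError("scale bounds must be positive")

    def to_dict(self) -> dict:
        return {"rotation_degrees": list(self.rotation_degrees),
                "flip_horizontal": self.flip_horizontal,
                "flip_vertical": self.flip_vertical,
                "scale_factor": list(self.scale_factor),
                "crop_fraction": self.crop_fraction,
                "seed": self.seed}


def _warp_pair(image: np.ndarray, mask: np.ndarray, angle_deg: float,
               scale: float) -> tuple[np.ndarray, np.ndarray]:
    h, w = image.shape
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    # forward map: p_out = s * R(angle) (p_in - c) + c  (xy order for skimage)
    fwd = (AffineTransform(translation=(-cx, -cy))
           + AffineTransform(rotation=math.radians(angle_deg), scale=scale)
           + AffineTransform(translation=(cx, cy)))
    img_w = warp(image, fwd.inverse, order=1, mode="constant", cval=0.0,
                 preserve_range=True)
    mask_w = warp(mask.astype(np.float64), fwd.inverse, order=0,
                  mode="constant", cval=0.0, preserve_range=True)
    return img_w, (mask_w > 0.5).astype(mask.dtype)


def augment_pair(image: np.ndarray, mask: np.ndarray, spec: AugmentSpec,
                 rng: np.random.Generator | None = None
                 ) -> tuple[np.ndarray, np.ndarray]:
    """Apply one random flip/rotate/scale/crop transform to both arrays.

    Passing an ``rng`` draws from that stream (on-the-fly training use);
    otherwise a fresh generator is seeded from ``spec.seed``.
    """
    if image.shape != mask.shape:
        raise ValueError(
            f"image {image.shape} and mask {mask.shape} dims must match")
    if not np.isin(mask, (0, 1)).all():
        raise ValueError("mask must be binary {0,1}")
    rng = rng if rng is not None else np.random.default_rng(spec.seed)
    h, w = image.shape

    if rng.uniform() < spec.flip_horizontal:
        image, mask = image[:, ::-1], mask[:, ::-1]
    if rng.uniform() < spec.flip_vertical:
        image, mask = image[::-1, :], mask[::-1, :]

    angle = rng.uniform(*spec.rotation_degrees)
    scale = rng.uniform(*spec.scale_factor)
    if angle != 0.0 or scale != 1.0:
        image, mask = _warp_pair(image, mask, angle, scale)

    if spec.crop_fraction < 1.0:
        ch = max(1, int(round(spec.crop_fraction * h)))
        cw = max(1, int(round(spec.crop_fraction * w)))
        top = int(rng.integers(0, h - ch + 1))
        left = int(rng.integers(0, w - cw + 1))
        image = image[top:top + ch, left:left + cw]
        mask = mask[top:top + ch, left:left + cw]
        image = resize(image, (h, w), order=1, preserve_range=True,
                       anti_aliasing=False)
        mask = (resize(mask.astype(np.float64), (h, w), order=0,
                       preserve_range=True, anti_aliasing=False)
                > 0.5).astype(mask.dtype)

    return np.ascontiguousarray(image), np.ascontiguousarray(mask)
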