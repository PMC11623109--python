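"""Synthetic B-mode breast-ultrasound phantoms with exact ground truth.

Each phantom is a speckle-textured grayscale image containing zero or more
hypoechoic (darker-than-background) lesions drawn as star-convex blobs —
ellipses with a sinusoidal radial perturbation whose amplitude controls
boundary irregularity — plus optional bright punctate calcifications and
posterior acoustic shadowing below lesions.  Speckle is modelled as
multiplicative gamma-distributed noise on a smooth background field, the
standard first-order approximation of fully developed B-mode speckle.

Class conventions mirror clinical reading: ``normal`` images contain no
lesion (empty mask), ``benign`` lesions have smooth boundaries, and
``malignant`` lesions are more irregular (higher radial perturbation,
spiculated outline) with more frequent calcifications and shadowing.

Everything is a pure function of (parameters, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter

__all__ = [
    "CLASS_LABELS",
    "PhantomParams",
    "Sample",
    "generate_lesion_mask",
    "render_ultrasound",
    "make_sample",
    "generate_dataset",
    "boundary_tortuosity",
]

CLASS_LABELS = ("normal", "benign", "malignant")

# class presets: (lesion count range, boundary irregularity, lesion
# contrast, calcification count range, shadow probability)
_CLASS_PRESETS = {
    "normal": ((0, 0), 0.0, 0.0, (0, 0), 0.0),
    "benign": ((1, 1), 0.06, 0.5, (0, 1), 0.3),
    "malignant": ((1, 2), 0.22, 0.6, (1, 3), 0.5),
}


@dataclass(frozen=True)
class PhantomParams:
    height: int = 256
    width: int = 256
    lesion_count_range: tuple[int, int] = (1, 1)
    lesion_radius_range: tuple[float, float] = (0.08, 0.22)  # fraction of min dim
    boundary_irregularity: float = 0.06
    lesion_contrast: float = 0.5
    speckle_shape: float = 4.0
    calcification_count_range: tuple[int, int] = (0, 1)
    shadow_probability: float = 0.3
    class_label: str = "benign"
    seed: int = 0

    def __post_init__(self):
        if self.class_label not in CLASS_LABELS:
            raise ValueError(f"unknown class label {self.class_label!r}")
        if self.class_label == "normal" and self.lesion_count_range != (0, 0):
            raise ValueError("normal class requires lesion_count_range (0, 0)")
        if not (0.0 <= self.lesion_contrast <= 1.0):
            raise ValueError("lesion_contrast must lie in [0, 1]")
        if self.speckle_shape <= 0:
            raise ValueError("speckle_shape must be positive")
        if self.boundary_irregularity < 0:
            raise ValueError("boundary_irregularity must be >= 0")
        if not (0.0 <= self.shadow_probability <= 1.0):
            raise ValueError("shadow_probability must lie in [0, 1]")
        lo, hi = self.lesion_radius_range
        if lo <= 0 or hi < lo:
            raise ValueError("bad lesion_radius_range")
        if hi >= 0.5:
            raise ValueError(
                f"lesion radius {hi} (fraction of frame) exceeds half the "
                f"frame; lesions must fit inside the image")

    @classmethod
    def for_class(cls, label: str, *, height: int = 256, width: int = 256,
                  seed: int = 0, **overrides) -> "PhantomParams":
        """Preset parameters for a clinical class (malignant boundaries are
        strictly more irregular than benign ones)."""
        counts, irr, contrast, calcs, shadow = _CLASS_PRESETS[label]
        base = cls(height=height, width=width, lesion_count_range=counts,
                   boundary_irregularity=irr, lesion_contrast=contrast,
                   calcification_count_range=calcs, shadow_probability=shadow,
                   class_label=label, seed=seed)
        return replace(base, **overrides) if overrides else base


@dataclass
class Sample:
    """An (image, mask, label) triple; image in [0,1], mask in {0,1}."""

    image: np.ndarray
    mask: np.ndarray
    label: str
    seed: int = 0

    def __post_init__(self):
        if self.image.shape != self.mask.shape:
            raise ValueError("image and mask dims must match")
        if not np.isin(self.mask, (0, 1)).all():
            raise ValueError("mask must be binary")


def _lesion_blob(rng: np.random.Generator, params: PhantomParams
                 ) -> np.ndarray:
    """One star-convex lesion as a boolean mask, fully inside the frame."""
    h, w = params.height, params.width
    mind = min(h, w)
    lo, hi = params.lesion_radius_range
    a = rng.uniform(lo, hi) * mind          # semi-axes, pixels
    b = rng.uniform(lo, hi) * mind
    theta = rng.uniform(0.0, math.pi)
    irr = params.boundary_irregularity
    # radial perturbation: low-order sinusoids, amplitude ~ irr * radius
    modes = np.arange(2, 7)
    amps = rng.normal(0.0, 1.0, size=modes.size)
    amps *= irr / max(np.abs(amps).sum(), 1e-9)
    phases = rng.uniform(0.0, 2 * math.pi, size=modes.size)
    rmax = max(a, b) * (1.0 + irr)
    margin = rmax + 2.0
    cy = rng.uniform(margin, h - margin)
    cx = rng.uniform(margin, w - margin)

    yy, xx = np.mgrid[0:h, 0:w]
    dy = yy - cy
    dx = xx - cx
    phi = np.arctan2(dy, dx)
    rho = np.hypot(dy, dx)
    # ellipse radius at angle phi (rotated by theta)
    c = np.cos(phi - theta)
    s = np.sin(phi - theta)
    r_ell = (a * b) / np.sqrt((b * c) ** 2 + (a * s) ** 2)
    bump = np.zeros_like(phi)
    for m, amp, ph in zip(modes, amps, phases):
        bump += amp * np.sin(m * phi + ph)
    r_bound = r_ell * (1.0 + bump)
    return rho <= r_bound


def generate_lesion_mask(params: PhantomParams) -> np.ndarray:
    """Union of the lesion blobs as a {0,1} uint8 mask (empty for the
    normal class); deterministic given ``params.seed``."""
    rng = np.random.default_rng(params.seed)
    lo, hi = params.lesion_count_range
    n = int(rng.integers(lo, hi + 1))
    mask = np.zeros((params.height, params.width), dtype=bool)
    for _ in range(n):
        mask |= _lesion_blob(rng, params)
    return mask.astype(np.uint8)


def render_ultrasound(mask: np.ndarray, params: PhantomParams) -> np.ndarray:
    """Render a B-mode-like image for a given lesion mask.

    Smooth background field x depth gain, lesion interior attenuated by
    (1 - lesion_contrast), multiplicative gamma speckle (mean 1, shape
    ``speckle_shape``), calcifications as bright discs of radius <= 3 px,
    and a posterior shadow column under each lesion with probability
    ``shadow_probability``.  Output is clipped to [0, 1].
    """
    h, w = params.height, params.width
    if mask.shape != (h, w):
        raise ValueError(f"mask shape {mask.shape} does not match params "
                         f"({h}, {w})")
    # independent stream so rendering noise never perturbs mask geometry
    rng = np.random.default_rng(np.random.SeedSequence(
        entropy=params.seed, spawn_key=(1,)))
    yy, xx = np.mgrid[0:h, 0:w]

    field = rng.normal(0.0, 1.0, size=(h, w))
    field = gaussian_filter(field, sigma=max(h, w) / 8.0)
    field /= max(np.abs(field).max(), 1e-9)
    depth_gain = 1.0 - 0.06 * (yy / max(h - 1, 1) - 0.5)
    base = (0.55 + 0.08 * field) * depth_gain

    soft = gaussian_filter(mask.astype(np.float64), sigma=1.0)
    echo = base * (1.0 - params.lesion_contrast * soft)

    # posterior shadowing: attenuate columns below each lesion's support
    if mask.any() and params.shadow_probability > 0:
        from scipy.ndimage import label as cc_label
        labels, n_blobs = cc_label(mask)
        shadow = np.ones((h, w))
        for blob in range(1, n_blobs + 1):
            if rng.uniform() >= params.shadow_probability:
                continue
            cols = np.nonzero((labels == blob).any(axis=0))[0]
            bottom = np.nonzero((labels == blob).any(axis=1))[0].max()
            lateral = np.exp(-0.5 * ((xx[0] - cols.mean()) /
                                     max(cols.size / 2.0, 1.0)) ** 2)
            depth_mask = (yy > bottom).astype(np.float64)
            shadow *= 1.0 - 0.45 * lateral[None, :] * depth_mask
        echo *= shadow

    speckle = rng.gamma(params.speckle_shape,
                        1.0 / params.speckle_shape, size=(h, w))
    img = echo * gaussian_filter(speckle, sigma=0.6)

    lo_c, hi_c = params.calcification_count_range
    n_calc = int(rng.integers(lo_c, hi_c + 1))
    if n_calc:
        inside = np.argwhere(mask > 0)
        for _ in range(n_calc):
            if inside.size:
                cy, cx = inside[rng.integers(0, len(inside))]
            else:
                cy = rng.integers(3, h - 3)
                cx = rng.integers(3, w - 3)
            r = rng.uniform(1.0, 3.0)
            disc = (yy - cy) ** 2 + (xx - cx) ** 2 <= r * r
            img[disc] += 0.6

    return np.clip(img, 0.0, 1.0)


def make_sample(params: PhantomParams) -> Sample:
    mask = generate_lesion_mask(params)
    image = render_ultrasound(mask, params)
    return Sample(image=image, mask=mask, label=params.class_label,
                  seed=params.seed)


def boundary_tortuosity(mask: np.ndarray) -> float:
    """Isoperimetric boundary roughness P^2 / (4 pi A); 1 for a disc,
    larger for irregular outlines.  0 for an empty mask."""
    from skimage.measure import perimeter
    area = float(np.count_nonzero(mask))
    if area == 0:
        return 0.0
    p = perimeter(mask > 0, neighborhood=8)
    return float(p * p / (4.0 * math.pi * area))


def generate_dataset(n_per_class: dict[str, int] | tuple[int, int, int],
                     out_dir: str | Path, *, height: int = 256,
                     width: int = 256, seed: int = 0,
                     overrides: dict | None = None):
    """Write a BUSI-style directory tree of phantoms and index it.

    Files follow the ``<class> (k).png`` / ``<class> (k)_mask.png`` naming;
    images are 8-bit grayscale, masks 8-bit {0, 255}.  Normal-class images
    get an all-zero mask file so every image has a mask on disk.  Returns
    the re-read :class:`~ultraseg.data.DatasetIndex` of the written tree.
    """
    import imageio.v3 as iio

    from .data import index_dataset

    if not isinstance(n_per_class, dict):
        n_per_class = dict(zip(("benign", "malignant", "normal"),
                               n_per_class))
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise OSError(f"cannot create dataset directory {out_dir}: {exc}")
    root_ss = np.random.SeedSequence(seed)
    for label in sorted(n_per_class):
        n = n_per_class[label]
        child = root_ss.spawn(1)[0]
        seeds = child.generate_state(max(n, 1)) % (2 ** 31)
        for k in range(1, n + 1):
            params = PhantomParams.for_class(
                label, height=height, width=width, seed=int(seeds[k - 1]),
                **(overrides or {}))
            sample = make_sample(params)
            img8 = np.round(sample.image * 255.0).astype(np.uint8)
            mask8 = (sample.mask * 255).astype(np.uint8)
            iio.imwrite(out_dir / f"{label} ({k}).png", img8)
            iio.imwrite(out_dir / f"{label} ({k})_mask.png", mask8)
    return index_dataset(out_dir)
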