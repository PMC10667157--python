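"""Seeded, label-consistent data augmentation for training pairs.

One geometric transform (flip, rotation, isotropic scaling, translation,
optional elastic deformation) is sampled per call and applied identically
to image and mask; the mask is always interpolated nearest-neighbour so
labels stay in {0, 1, 2}, and pixels pulled in from outside the canvas are
filled with background. Intensity transforms (gamma, additive noise) touch
only the image. Everything is deterministic for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage


@dataclass(frozen=True)
class AugmentPolicy:
    """Augmentation hyperparameters; ``enabled=False`` is the identity."""

    p_flip_lr: float = 0.5
    rotation_deg_range: tuple[float, float] = (-10.0, 10.0)
    scale_range: tuple[float, float] = (0.9, 1.1)
    translation_px_range: tuple[float, float] = (-12.0, 12.0)
    elastic_alpha: float = 30.0
    elastic_sigma: float = 6.0
    p_elastic: float = 0.3
    gamma_range: tuple[float, float] = (0.8, 1.25)
    additive_noise_sigma: float = 0.01
    enabled: bool = True

    def __post_init__(self) -> None:
        for name in ("p_flip_lr", "p_elastic"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {getattr(self, name)}")
        for name in ("rotation_deg_range", "scale_range", "translation_px_range", "gamma_range"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"{name} must be well-ordered, got {(lo, hi)}")
        if self.additive_noise_sigma < 0 or self.elastic_alpha < 0 or self.elastic_sigma <= 0:
            raise ValueError("noise/elastic parameters must be non-negative (sigma positive)")


def _affine_coords(shape, angle_deg, scale, shift, rng=None):
    h, w = shape
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    th = np.deg2rad(angle_deg)
    # inverse map: output pixel -> input pixel
    rot = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]]) / scale
    rows, cols = np.meshgrid(np.arange(h, dtype=float), np.arange(w, dtype=float), indexing="ij")
    dy, dx = rows - cy - shift[0], cols - cx - shift[1]
    src_r = rot[0, 0] * dy + rot[0, 1] * dx + cy
    src_c = rot[1, 0] * dy + rot[1, 1] * dx + cx
    return src_r, src_c


def augment_pair(
    image: np.ndarray, mask: np.ndarray, policy: AugmentPolicy, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """Apply one sampled augmentation to an (image, mask) pair.

    The same geometric transform hits both arrays; labels are preserved
    exactly under pure flips and right-angle rotations.
    """
    image = np.asarray(image, dtype=np.float32)
    mask = np.asarray(mask)
    if image.shape != mask.shape:
        raise ValueError(f"image {image.shape} and mask {mask.shape} must share shape")
    if not policy.enabled:
        return image.copy(), mask.copy()
    rng = np.random.default_rng(seed)

    if rng.uniform() < policy.p_flip_lr:
        image = image[:, ::-1]
        mask = mask[:, ::-1]

    angle = rng.uniform(*policy.rotation_deg_range)
    scale = rng.uniform(*policy.scale_range)
    shift = rng.uniform(*policy.translation_px_range, size=2)
    src_r, src_c = _affine_coords(image.shape, angle, scale, shift)

    if rng.uniform() < policy.p_elastic and policy.elastic_alpha > 0:
        for arr in (src_r, src_c):
            d = rng.normal(0, 1, size=image.shape)
            arr += policy.elastic_alpha * ndimage.gaussian_filter(d, policy.elastic_sigma, mode="constant")

    coords = np.stack([src_r, src_c])
    image = ndimage.map_coordinates(image, coords, order=1, mode="constant", cval=0.0)
    mask = ndimage.map_coordinates(mask, coords, order=0, mode="constant", cval=0).astype(mask.dtype)

    glo, ghi = policy.gamma_range
    if (glo, ghi) != (1.0, 1.0):
        gamma = rng.uniform(glo, ghi)
        peak = image.max()
        if peak > 0:
            image = peak * (image / peak) ** gamma
    if policy.additive_noise_sigma > 0:
        image = image + rng.normal(0, policy.additive_noise_sigma, size=image.shape)

    return image.astype(np.float32), mask
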