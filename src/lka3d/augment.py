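"""On-the-fly 3D data augmentation.

Each transform fires independently with a preset probability and draws
its parameters from a preset range; spatial transforms (scaling,
rotation, elastic deformation, flipping) are applied identically to
image (trilinear) and label (nearest-neighbour), intensity transforms
touch only the image.  All randomness comes from a caller-provided seed.

Defaults:

=================  ===========  ==========================
transform          probability  parameter range
=================  ===========  ==========================
brightness         0.30         factor U(0.7, 1.3)
contrast           0.15         factor U(0.6, 1.4)
gaussian noise     0.15         sigma U(0, 1)
gaussian blur      0.20         kernel sigma U(0.5, 1.5)
gamma              0.15         gamma U(0.7, 1.5)
scaling            0.30         factor U(0.65, 1.6)
rotation           0.30         U(-30, 30) degrees
elastic            0.30         alpha U(5, 10), sigma 3*alpha
flipping           0.50         each axis independently
=================  ===========  ==========================
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .io import VolumeSample

__all__ = ["AugmentationPolicy", "augment"]


def _check_range(name, rng_pair):
    lo, hi = rng_pair
    if lo > hi:
        raise ValueError(f"{name}: range must be ordered, got ({lo}, {hi})")
    return (float(lo), float(hi))


@dataclass
class AugmentationPolicy:
    p_brightness: float = 0.30
    brightness_range: tuple[float, float] = (0.7, 1.3)
    p_contrast: float = 0.15
    contrast_range: tuple[float, float] = (0.6, 1.4)
    p_noise: float = 0.15
    noise_sigma_range: tuple[float, float] = (0.0, 1.0)
    p_blur: float = 0.20
    blur_sigma_range: tuple[float, float] = (0.5, 1.5)
    p_gamma: float = 0.15
    gamma_range: tuple[float, float] = (0.7, 1.5)
    p_scale: float = 0.30
    scale_range: tuple[float, float] = (0.65, 1.6)
    p_rotate: float = 0.30
    rotate_deg_range: tuple[float, float] = (-30.0, 30.0)
    p_elastic: float = 0.30
    elastic_alpha_range: tuple[float, float] = (5.0, 10.0)
    elastic_sigma_factor: float = 3.0
    p_flip: float = 0.50

    def __post_init__(self):
        for name in ("p_brightness", "p_contrast", "p_noise", "p_blur", "p_gamma",
                     "p_scale", "p_rotate", "p_elastic", "p_flip"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be a probability, got {v}")
        for name in ("brightness_range", "contrast_range", "noise_sigma_range",
                     "blur_sigma_range", "gamma_range", "scale_range",
                     "rotate_deg_range", "elastic_alpha_range"):
            setattr(self, name, _check_range(name, getattr(self, name)))

    @classmethod
    def identity(cls) -> "AugmentationPolicy":
        """All probabilities zero: augment() becomes the identity."""
        return cls(p_brightness=0, p_contrast=0, p_noise=0, p_blur=0, p_gamma=0,
                   p_scale=0, p_rotate=0, p_elastic=0, p_flip=0)


def _warp(image, label, coords):
    img = np.stack([
        ndimage.map_coordinates(image[c], coords, order=1, mode="nearest")
        for c in range(image.shape[0])
    ])
    lab = None
    if label is not None:
        lab = ndimage.map_coordinates(label, coords, order=0, mode="nearest")
    return img, lab


def _affine_coords(shape, matrix):
    """Sampling coordinates for an affine about the volume center."""
    center = (np.asarray(shape) - 1) / 2.0
    grid = np.indices(shape, dtype=np.float32).reshape(3, -1)
    rel = grid - center[:, None]
    src = matrix @ rel + center[:, None]
    return src.reshape((3,) + tuple(shape))


def augment(sample: VolumeSample, policy: AugmentationPolicy, seed: int
            ) -> VolumeSample:
    """Apply one random draw of the augmentation policy (seeded)."""
    rng = np.random.default_rng(seed)
    image = sample.image.astype(np.float32, copy=True)
    label = None if sample.label is None else sample.label.copy()

    # intensity transforms (label untouched)
    if rng.random() < policy.p_brightness:
        image *= rng.uniform(*policy.brightness_range)
    if rng.random() < policy.p_contrast:
        f = rng.uniform(*policy.contrast_range)
        mean = image.mean(axis=(1, 2, 3), keepdims=True)
        image = mean + (image - mean) * f
    if rng.random() < policy.p_noise:
        sigma = rng.uniform(*policy.noise_sigma_range)
        image += rng.normal(0.0, sigma, size=image.shape).astype(np.float32)
    if rng.random() < policy.p_blur:
        sigma = rng.uniform(*policy.blur_sigma_range)
        for c in range(image.shape[0]):
            image[c] = ndimage.gaussian_filter(image[c], sigma)
    if rng.random() < policy.p_gamma:
        gamma = rng.uniform(*policy.gamma_range)
        lo = image.min(axis=(1, 2, 3), keepdims=True)
        hi = image.max(axis=(1, 2, 3), keepdims=True)
        span = np.where(hi > lo, hi - lo, 1.0)
        image = ((image - lo) / span) ** gamma * span + lo

    # spatial transforms (image trilinear, label nearest)
    if rng.random() < policy.p_scale:
        f = rng.uniform(*policy.scale_range)
        coords = _affine_coords(sample.shape, np.eye(3) / f)
        image, label = _warp(image, label, coords)
    if rng.random() < policy.p_rotate:
        angles = np.deg2rad(rng.uniform(*policy.rotate_deg_range, size=3))
        rots = []
        for ax, ang in enumerate(angles):
            c, s = np.cos(ang), np.sin(ang)
            m = np.eye(3)
            i, j = [a for a in range(3) if a != ax]
            m[i, i], m[i, j], m[j, i], m[j, j] = c, -s, s, c
            rots.append(m)
        matrix = rots[0] @ rots[1] @ rots[2]
        coords = _affine_coords(sample.shape, matrix.T)
        image, label = _warp(image, label, coords)
    if rng.random() < policy.p_elastic:
        alpha = rng.uniform(*policy.elastic_alpha_range)
        sigma = policy.elastic_sigma_factor * alpha
        disp = [
            ndimage.gaussian_filter(
                rng.uniform(-1.0, 1.0, size=sample.shape), sigma
            ) * alpha
            for _ in range(3)
        ]
        grid = np.indices(sample.shape, dtype=np.float32)
        coords = grid + np.stack(disp).astype(np.float32)
        image, label = _warp(image, label, coords)
    if rng.random() < policy.p_flip:
        for ax in range(3):
            if rng.random() < 0.5:
                image = np.flip(image, axis=1 + ax)
                if label is not None:
                    label = np.flip(label, axis=ax)

    out = sample.copy()
    out.image = np.ascontiguousarray(image, dtype=np.float32)
    out.label = None if label is None else np.ascontiguousarray(label)
    return out
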