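"""Synthetic multi-class phantom volumes for testing without clinical data.

A phantom is a noisy background populated with ellipsoidal "organ" blobs,
one intensity band per class, and the matching integer label volume.
Blobs are placed by rejection sampling so classes never overlap.  The
same seed always yields bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import VolumeSample

__all__ = ["PhantomConfig", "generate_phantom"]


@dataclass(frozen=True)
class PhantomConfig:
    shape: tuple[int, int, int] = (64, 64, 64)
    n_classes: int = 3  # foreground classes; labels run 0..n_classes
    blobs_per_class: int = 2
    radius_range: tuple[float, float] = (5.0, 10.0)
    class_means: tuple[float, ...] | None = None  # default: spread over [0.4, 1.0]
    intensity_sigma: float = 0.05
    noise_sigma: float = 0.05
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    seed: int = 0
    max_tries: int = 200

    def means(self) -> np.ndarray:
        if self.class_means is not None:
            if len(self.class_means) != self.n_classes:
                raise ValueError(
                    f"{len(self.class_means)} means for {self.n_classes} classes"
                )
            return np.asarray(self.class_means, dtype=np.float32)
        return np.linspace(0.4, 1.0, self.n_classes, dtype=np.float32)


def _ellipsoid_mask(shape, center, semiaxes) -> np.ndarray:
    grids = np.indices(shape, dtype=np.float32)
    q = sum(((g - c) / a) ** 2 for g, c, a in zip(grids, center, semiaxes))
    return q <= 1.0


def generate_phantom(config: PhantomConfig) -> VolumeSample:
    """Generate one phantom VolumeSample (1-channel image + labels)."""
    if config.n_classes < 1:
        raise ValueError("need at least one foreground class")
    rng = np.random.default_rng(config.seed)
    shape = tuple(int(s) for s in config.shape)
    label = np.zeros(shape, dtype=np.int16)
    means = config.means()

    for cls in range(1, config.n_classes + 1):
        placed = 0
        tries = 0
        while placed < config.blobs_per_class:
            tries += 1
            if tries > config.max_tries:
                raise RuntimeError(
                    f"could not place blob {placed + 1} of class {cls} within "
                    f"{config.max_tries} tries (grid too small for "
                    f"non-overlapping radii {config.radius_range})"
                )
            semiaxes = rng.uniform(*config.radius_range, size=3)
            center = [rng.uniform(a, s - 1 - a) if s - 1 > 2 * a else (s - 1) / 2
                      for s, a in zip(shape, semiaxes)]
            mask = _ellipsoid_mask(shape, center, semiaxes)
            if not mask.any() or (label[mask] != 0).any():
                continue
            label[mask] = cls
            placed += 1

    image = rng.normal(0.0, config.noise_sigma, size=shape).astype(np.float32)
    for cls in range(1, config.n_classes + 1):
        m = label == cls
        image[m] = means[cls - 1] + rng.normal(
            0.0, config.intensity_sigma, size=int(m.sum())
        ).astype(np.float32)

    return VolumeSample(
        image=image[None],
        spacing=config.spacing,
        affine=np.diag(list(config.spacing) + [1.0]),
        identifier=f"phantom-{config.seed}",
        label=label,
    )
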