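"""Preprocessing: spacing resampling with anti-alias smoothing, center
crop/pad with a recorded inverse, and intensity normalisation."""

from __future__ import annotations

import warnings

import numpy as np
from scipy import ndimage

from .io import VolumeSample

__all__ = [
    "resample_volume",
    "crop_or_pad",
    "restore_to_original_grid",
    "normalize_intensity",
]


def resample_volume(sample: VolumeSample, target_spacing, antialias: bool = True
                    ) -> VolumeSample:
    """Resample to `target_spacing` (mm).

    Images are Gaussian-smoothed before interpolation wherever the grid is
    coarsened (sigma = downsampling factor / 3 per axis) and then
    trilinearly interpolated; labels are nearest-neighbour resampled with
    no smoothing.  Output dims are round(dims * spacing / target).
    """
    target = tuple(float(t) for t in target_spacing)
    if any(t <= 0 for t in target):
        raise ValueError(f"target spacing must be positive: {target}")
    old_shape = sample.shape
    new_shape = tuple(
        int(round(s * sp / t)) for s, sp, t in zip(old_shape, sample.spacing, target)
    )
    if any(s < 1 for s in new_shape):
        raise ValueError(f"resampling to {target} collapses the grid: {new_shape}")
    factors = [t / sp for sp, t in zip(sample.spacing, target)]  # >1 = coarsening
    zoom = [n / o for n, o in zip(new_shape, old_shape)]

    channels = []
    for c in range(sample.channels):
        vol = sample.image[c]
        if antialias and any(f > 1.0 for f in factors):
            sigma = [f / 3.0 if f > 1.0 else 0.0 for f in factors]
            vol = ndimage.gaussian_filter(vol, sigma=sigma)
        channels.append(ndimage.zoom(vol, zoom, order=1, grid_mode=True, mode="nearest"))
    image = np.stack(channels)

    label = None
    if sample.label is not None:
        label = ndimage.zoom(
            sample.label, zoom, order=0, grid_mode=True, mode="nearest"
        ).astype(sample.label.dtype)

    scale = np.array([o / n for o, n in zip(old_shape, new_shape)])
    affine = sample.affine.copy()
    affine[:3, :3] = affine[:3, :3] @ np.diag(scale)
    out = VolumeSample(
        image=image, spacing=target, affine=affine,
        identifier=sample.identifier, label=label, meta=dict(sample.meta),
    )
    out.meta["resampled_from"] = {"shape": old_shape, "spacing": sample.spacing}
    return out


def crop_or_pad(sample: VolumeSample, target_shape) -> VolumeSample:
    """Center crop and/or zero-pad to `target_shape`, recording the inverse."""
    target = tuple(int(t) for t in target_shape)
    if any(t < 1 for t in target):
        raise ValueError(f"target shape must be positive: {target}")
    src = sample.shape
    crop_start = [max(0, (s - t) // 2) for s, t in zip(src, target)]
    pad_before = [max(0, (t - s) // 2) for s, t in zip(src, target)]

    def _place(vol, fill=0):
        out = np.full(target, fill, dtype=vol.dtype)
        src_sl, dst_sl = [], []
        for ax in range(3):
            n = min(src[ax], target[ax])
            src_sl.append(slice(crop_start[ax], crop_start[ax] + n))
            dst_sl.append(slice(pad_before[ax], pad_before[ax] + n))
        out[tuple(dst_sl)] = vol[tuple(src_sl)]
        return out

    image = np.stack([_place(sample.image[c]) for c in range(sample.channels)])
    label = None if sample.label is None else _place(sample.label)
    out = VolumeSample(
        image=image, spacing=sample.spacing, affine=sample.affine.copy(),
        identifier=sample.identifier, label=label, meta=dict(sample.meta),
    )
    out.meta["crop_or_pad"] = {
        "original_shape": src,
        "crop_start": crop_start,
        "pad_before": pad_before,
    }
    return out


def restore_to_original_grid(volume: np.ndarray, meta: dict, fill=0) -> np.ndarray:
    """Map a cropped/padded prediction back onto the pre-crop grid."""
    info = meta["crop_or_pad"]
    src = tuple(info["original_shape"])
    crop_start, pad_before = info["crop_start"], info["pad_before"]
    out = np.full(src, fill, dtype=volume.dtype)
    for_sl, back_sl = [], []
    for ax in range(3):
        n = min(src[ax], volume.shape[ax])
        for_sl.append(slice(pad_before[ax], pad_before[ax] + n))
        back_sl.append(slice(crop_start[ax], crop_start[ax] + n))
    out[tuple(back_sl)] = volume[tuple(for_sl)]
    return out


def normalize_intensity(sample: VolumeSample, mode: str = "mri",
                        clip_percentiles=(0.5, 99.5)) -> VolumeSample:
    """Per-channel intensity normalisation.

    ``mode="mri"``: z-score over the nonzero (masked) voxels, background
    left at zero.  ``mode="ct"``: clip to the given intensity percentiles,
    then z-score over the whole volume.  Zero-variance channels are
    centred but not scaled, with a warning.
    """
    if mode not in ("mri", "ct"):
        raise ValueError(f"unknown normalisation mode {mode!r}")
    image = sample.image.copy()
    for c in range(image.shape[0]):
        vol = image[c]
        if not np.all(np.isfinite(vol)):
            raise ValueError(f"channel {c} contains non-finite intensities")
        if mode == "mri":
            mask = vol != 0
            region = vol[mask] if mask.any() else vol.ravel()
        else:
            lo, hi = np.percentile(vol, clip_percentiles)
            vol = np.clip(vol, lo, hi)
            mask = np.ones(vol.shape, dtype=bool)
            region = vol.ravel()
        mu, sd = float(region.mean()), float(region.std())
        if sd == 0.0:
            warnings.warn(
                f"channel {c}: zero variance in normalisation region; centred only"
            )
            vol = np.where(mask, vol - mu, vol)
        else:
            vol = np.where(mask, (vol - mu) / sd, vol)
        image[c] = vol
    out = sample.copy()
    out.image = image.astype(np.float32)
    return out
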