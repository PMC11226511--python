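"""NIfTI volume I/O and the VolumeSample container.

A VolumeSample carries a (channel, depth, height, width) float32 image,
an optional integer label volume on the same grid, the voxel spacing in
millimetres, and the NIfTI affine (carried opaquely — no implicit
reorientation).  Array axes follow the file's (i, j, k) order, referred
to as (depth, height, width) throughout the package.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = ["VolumeSample", "read_volume", "write_volume", "write_label", "attach_label"]


@dataclass
class VolumeSample:
    image: np.ndarray  # (C, D, H, W) float32
    spacing: tuple[float, float, float]
    affine: np.ndarray
    identifier: str = ""
    label: np.ndarray | None = None  # (D, H, W) int
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.image = np.asarray(self.image, dtype=np.float32)
        if self.image.ndim != 4:
            raise ValueError(f"image must be (C, D, H, W), got shape {self.image.shape}")
        self.spacing = tuple(float(s) for s in self.spacing)
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be strictly positive: {self.spacing}")
        if self.label is not None:
            self.label = np.asarray(self.label)
            if self.label.shape != self.image.shape[1:]:
                raise ValueError(
                    f"label shape {self.label.shape} differs from image grid "
                    f"{self.image.shape[1:]}"
                )

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.image.shape[1:]

    @property
    def channels(self) -> int:
        return self.image.shape[0]

    def copy(self) -> "VolumeSample":
        return VolumeSample(
            image=self.image.copy(),
            spacing=self.spacing,
            affine=self.affine.copy(),
            identifier=self.identifier,
            label=None if self.label is None else self.label.copy(),
            meta=dict(self.meta),
        )


def read_volume(path, label_path=None, identifier: str | None = None) -> VolumeSample:
    """Read a 3-D or 4-D NIfTI image (and optionally a label volume)."""
    path = Path(path)
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim == 3:
        data = data[None]
    elif data.ndim == 4:
        data = np.moveaxis(data, -1, 0)  # modalities last in file, first in memory
    else:
        raise ValueError(f"{path}: expected 3-D or 4-D data, got {data.ndim}-D")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    sample = VolumeSample(
        image=data.astype(np.float32),
        spacing=spacing,
        affine=np.asarray(img.affine, dtype=float),
        identifier=identifier or path.name.split(".")[0],
    )
    if label_path is not None:
        attach_label(sample, label_path)
    return sample


def attach_label(sample: VolumeSample, path) -> VolumeSample:
    lab = nib.load(str(path))
    data = np.asanyarray(lab.dataobj)
    if data.ndim != 3:
        raise ValueError(f"{path}: label must be 3-D, got {data.ndim}-D")
    if data.shape != sample.shape:
        raise ValueError(
            f"label grid {data.shape} does not match image grid {sample.shape}"
        )
    sample.label = np.rint(data).astype(np.int16)
    return sample


def _nifti(data: np.ndarray, sample: VolumeSample) -> nib.Nifti1Image:
    img = nib.Nifti1Image(data, sample.affine)
    img.header.set_zooms(tuple(sample.spacing) + ((1.0,) if data.ndim == 4 else ()))
    return img


def write_volume(sample: VolumeSample, path) -> None:
    """Write the image; multi-channel volumes go to a 4-D file."""
    data = sample.image
    data = data[0] if data.shape[0] == 1 else np.moveaxis(data, 0, -1)
    nib.save(_nifti(np.asarray(data, dtype=np.float32), sample), str(path))


def write_label(sample: VolumeSample, path, label: np.ndarray | None = None) -> None:
    lab = sample.label if label is None else label
    if lab is None:
        raise ValueError("sample has no label volume")
    nib.save(_nifti(np.asarray(lab, dtype=np.int16), sample), str(path))
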