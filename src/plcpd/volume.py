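"""3D scalar volumes with physical grid metadata, and NIfTI/MetaImage I/O.

The voxel grid is indexed (i, j, k) with world coordinate
``origin + index * spacing`` (mm, 0-based indices).  Intensities are kept in
floating point throughout; no 8-bit quantization is applied anywhere in the
pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import SimpleITK as sitk

__all__ = ["Volume3D", "read_volume", "write_volume"]

_MIN_SHAPE = 8  # smallest edge for which the filter bank is meaningful


@dataclass
class Volume3D:
    """Scalar voxel grid with spacing (mm/voxel) and world origin (mm)."""

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    axis_order: str = field(default="ijk")

    def __post_init__(self) -> None:
        arr = np.asarray(self.data, dtype=float)
        if arr.ndim != 3:
            raise ValueError(f"expected 3 dimensions, found {arr.ndim}")
        if min(arr.shape) < _MIN_SHAPE:
            raise ValueError(
                f"volume shape {arr.shape} too small; every edge must be >= {_MIN_SHAPE}"
            )
        if not np.all(np.isfinite(arr)):
            raise ValueError("volume contains non-finite values")
        sp = tuple(float(s) for s in self.spacing)
        if len(sp) != 3 or any(s <= 0 for s in sp):
            raise ValueError(f"spacing must be three positive values, got {self.spacing}")
        self.data = arr
        self.spacing = sp
        self.origin = tuple(float(o) for o in self.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def world_coordinates(self, indices: np.ndarray) -> np.ndarray:
        """World mm positions of (N, 3) fractional voxel indices."""
        return np.asarray(self.origin) + np.asarray(indices, float) * np.asarray(
            self.spacing
        )

    def with_data(self, data: np.ndarray) -> "Volume3D":
        """Same grid, new intensities."""
        return Volume3D(
            data=data, spacing=self.spacing, origin=self.origin, axis_order=self.axis_order
        )


def read_volume(path: str | Path) -> Volume3D:
    """Load a NIfTI (.nii/.nii.gz) or MetaImage (.mhd/.mha) volume.

    Spacing and origin are taken from the header; intensities are cast to
    floating point without rescaling.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    name = path.name.lower()
    if name.endswith((".nii", ".nii.gz")):
        img = nib.load(str(path))
        arr = np.asarray(img.dataobj, dtype=float)
        if arr.ndim != 3:
            raise ValueError(f"{path}: expected 3 dimensions, found {arr.ndim}")
        spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
        origin = tuple(float(v) for v in img.affine[:3, 3])
        return Volume3D(arr, spacing=spacing, origin=origin)
    if name.endswith((".mhd", ".mha")):
        img = sitk.ReadImage(str(path))
        if img.GetDimension() != 3:
            raise ValueError(f"{path}: expected 3 dimensions, found {img.GetDimension()}")
        # SimpleITK arrays come back (k, j, i); transpose to (i, j, k).
        arr = sitk.GetArrayFromImage(img).astype(float).transpose(2, 1, 0)
        return Volume3D(
            arr,
            spacing=tuple(float(s) for s in img.GetSpacing()),
            origin=tuple(float(o) for o in img.GetOrigin()),
        )
    raise ValueError(f"{path}: unsupported volume format (need .nii/.nii.gz/.mhd/.mha)")


def write_volume(vol: Volume3D, path: str | Path) -> None:
    """Write a volume as NIfTI or MetaImage, preserving spacing and origin."""
    path = Path(path)
    name = path.name.lower()
    if name.endswith((".nii", ".nii.gz")):
        affine = np.diag(list(vol.spacing) + [1.0])
        affine[:3, 3] = vol.origin
        nib.save(nib.Nifti1Image(vol.data, affine), str(path))
    elif name.endswith((".mhd", ".mha")):
        img = sitk.GetImageFromArray(vol.data.transpose(2, 1, 0))
        img.SetSpacing(vol.spacing)
        img.SetOrigin(vol.origin)
        sitk.WriteImage(img, str(path))
    else:
        raise ValueError(f"{path}: unsupported volume format (need .nii/.nii.gz/.mhd/.mha)")
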