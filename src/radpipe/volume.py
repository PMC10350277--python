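"""In-memory containers for 3D MRI volumes and binary tumor masks.

An :class:`ImageVolume` is a 3D scalar grid with per-axis voxel spacing in
millimetres and a modality tag (``"T1w"`` / ``"T2w"``).  A :class:`RoiMask`
is a binary mask defined on the same grid.  Axis convention throughout the
package: axes 0 and 1 are the in-plane (x, y) directions, axis 2 is the
slice (z) direction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

__all__ = ["ImageVolume", "RoiMask", "load_nifti_volume", "load_nifti_mask"]


@dataclass
class ImageVolume:
    """3D scalar intensity grid with physical voxel spacing.

    Parameters
    ----------
    data : ndarray, shape (nx, ny, nz)
        Voxel intensities.
    spacing : tuple of float
        Voxel spacing in mm per axis; anisotropic spacing is allowed.
    modality : str
        Free-form modality tag, conventionally ``"T1w"`` or ``"T2w"``.
    """

    data: np.ndarray
    spacing: tuple[float, float, float]
    modality: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3D volume, got ndim={self.data.ndim}")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be 3 positive floats, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume(self) -> float:
        """Physical volume of one voxel in mm^3."""
        return float(np.prod(self.spacing))

    def with_data(self, data: np.ndarray) -> "ImageVolume":
        """New volume on the same grid with different intensities."""
        return ImageVolume(data, self.spacing, self.modality)

    def to_nifti(self, path: str) -> None:
        affine = np.diag(list(self.spacing) + [1.0])
        nib.save(nib.Nifti1Image(self.data.astype(np.float32), affine), path)


@dataclass
class RoiMask:
    """Binary tumor mask on the same grid as its image volume."""

    data: np.ndarray
    spacing: tuple[float, float, float] = field(default=(1.0, 1.0, 1.0))

    def __post_init__(self) -> None:
        arr = np.asarray(self.data)
        uniq = np.unique(arr)
        if not np.all(np.isin(uniq, (0, 1))):
            raise ValueError("mask must be binary (0/1)")
        self.data = arr.astype(bool)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3D mask, got ndim={self.data.ndim}")
        self.spacing = tuple(float(s) for s in self.spacing)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())

    @property
    def volume_mm3(self) -> float:
        return self.n_voxels * float(np.prod(self.spacing))

    def bounding_box_lengths(self) -> tuple[int, int, int]:
        """Side lengths (voxels) of the tight bounding box of the mask."""
        if self.n_voxels == 0:
            raise ValueError("empty mask has no bounding box")
        idx = np.nonzero(self.data)
        return tuple(int(ax.max() - ax.min() + 1) for ax in idx)

    def to_nifti(self, path: str) -> None:
        affine = np.diag(list(self.spacing) + [1.0])
        nib.save(nib.Nifti1Image(self.data.astype(np.uint8), affine), path)


def _spacing_from_header(img: nib.Nifti1Image) -> tuple[float, float, float]:
    zooms = img.header.get_zooms()[:3]
    return tuple(float(z) for z in zooms)


def load_nifti_volume(path: str, modality: str = "") -> ImageVolume:
    """Load a NIfTI file as an :class:`ImageVolume`, spacing from the header."""
    img = nib.load(path)
    return ImageVolume(np.asanyarray(img.dataobj, dtype=float),
                       _spacing_from_header(img), modality)


def load_nifti_mask(path: str) -> RoiMask:
    """Load a NIfTI file as a binary :class:`RoiMask` (values must be 0/1)."""
    img = nib.load(path)
    return RoiMask(np.asanyarray(img.dataobj), _spacing_from_header(img))
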