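"""Volumetric containers and NIfTI I/O.

Axis convention throughout the package: array axis 0 = x (subject left->right),
axis 1 = y (posterior->anterior), axis 2 = z (inferior->superior), i.e. a
right-handed RAS-like grid. All volumes produced here carry a diagonal
voxel->world affine; loaded volumes are reoriented to the closest canonical
orientation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = ["CTVolume", "load_volume", "save_volume", "save_mask", "load_mask"]


@dataclass
class CTVolume:
    """A 3D scalar image in Hounsfield units with geometry metadata.

    Parameters
    ----------
    data : ndarray, shape (nx, ny, nz)
        Voxel intensities in HU.
    spacing : tuple of float
        Voxel size per axis in mm; strictly positive.
    affine : ndarray (4, 4), optional
        Voxel-index to world-coordinate map. Defaults to a diagonal affine
        that puts the world origin at the grid centre.
    """

    data: np.ndarray
    spacing: tuple[float, float, float]
    affine: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError("CTVolume data must be 3D")
        self.spacing = tuple(float(s) for s in self.spacing)
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be positive")
        if self.affine is None:
            self.affine = centered_affine(self.data.shape, self.spacing)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise ValueError("affine must be invertible")
        if not np.isfinite(self.data).all():
            raise ValueError("data must be finite")

    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(self.data.shape)  # type: ignore[return-value]

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def voxel_to_world(self, idx: np.ndarray) -> np.ndarray:
        """Map voxel indices (..., 3) to world coordinates in mm."""
        idx = np.asarray(idx, dtype=float)
        return idx @ self.affine[:3, :3].T + self.affine[:3, 3]

    def world_to_voxel(self, xyz: np.ndarray) -> np.ndarray:
        inv = np.linalg.inv(self.affine)
        xyz = np.asarray(xyz, dtype=float)
        return xyz @ inv[:3, :3].T + inv[:3, 3]

    def like(self, data: np.ndarray) -> "CTVolume":
        """A new volume on the same grid with different voxel data."""
        return CTVolume(data=data, spacing=self.spacing, affine=self.affine.copy())


def centered_affine(shape, spacing) -> np.ndarray:
    """Diagonal affine placing the world origin at the centre of the grid."""
    aff = np.eye(4)
    for i in range(3):
        aff[i, i] = spacing[i]
        aff[i, 3] = -(shape[i] - 1) / 2.0 * spacing[i]
    return aff


def mask_volume_ml(mask: np.ndarray, spacing) -> float:
    """Volume of a binary mask in mL (voxel count x voxel volume / 1000)."""
    return float(np.count_nonzero(mask)) * float(np.prod(spacing)) / 1000.0


def save_volume(vol: CTVolume, path: str | Path, dtype=np.float32) -> None:
    img = nib.Nifti1Image(np.asarray(vol.data, dtype=dtype), vol.affine)
    img.header.set_zooms(vol.spacing)
    nib.save(img, str(path))


def save_mask(mask: np.ndarray, ref: CTVolume, path: str | Path) -> None:
    save_volume(ref.like(mask.astype(np.uint8)), path, dtype=np.uint8)


def load_volume(path: str | Path) -> CTVolume:
    img = nib.as_closest_canonical(nib.load(str(path)))
    data = np.asarray(img.get_fdata(), dtype=np.float32)
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return CTVolume(data=data, spacing=spacing, affine=np.asarray(img.affine))


def load_mask(path: str | Path) -> np.ndarray:
    return load_volume(path).data > 0.5
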