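"""Scalar voxel volume container standing in for CT images.

Axis order is (x, y, z); the world position of voxel ``(i, j, k)`` is
``origin + index * spacing`` (voxel centers, 0-based indices, isotropic
spacing in mm).  I/O goes through SimpleITK so volumes round-trip as
NIfTI-1 (``.nii``/``.nii.gz``) or MetaImage (``.mha``/``.mhd``) with the
spacing and origin recorded in the header.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import SimpleITK as sitk

__all__ = ["VoxelVolume"]


@dataclass
class VoxelVolume:
    data: np.ndarray  # (nx, ny, nz) scalar array
    spacing: float  # mm, isotropic
    origin: np.ndarray  # world position of voxel (0,0,0) center, mm

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError("volume data must be 3-D")
        if self.spacing <= 0:
            raise ValueError("spacing must be positive")
        self.origin = np.asarray(self.origin, dtype=float)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def world_to_index(self, points: np.ndarray) -> np.ndarray:
        """Continuous (fractional) voxel indices of world-space points."""
        return (np.atleast_2d(points) - self.origin) / self.spacing

    def index_to_world(self, idx: np.ndarray) -> np.ndarray:
        return np.atleast_2d(idx) * self.spacing + self.origin

    def copy(self) -> "VoxelVolume":
        return VoxelVolume(self.data.copy(), self.spacing, self.origin.copy())

    def save(self, path: str | Path) -> None:
        img = sitk.GetImageFromArray(np.ascontiguousarray(self.data.T))
        img.SetSpacing((self.spacing,) * 3)
        img.SetOrigin(tuple(self.origin))
        sitk.WriteImage(img, str(path))

    @classmethod
    def load(cls, path: str | Path) -> "VoxelVolume":
        img = sitk.ReadImage(str(path))
        spacing = img.GetSpacing()
        if not np.allclose(spacing, spacing[0], atol=1e-6):
            raise ValueError("only isotropic volumes are supported")
        data = sitk.GetArrayFromImage(img).T
        return cls(data, float(spacing[0]), np.array(img.GetOrigin()))
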