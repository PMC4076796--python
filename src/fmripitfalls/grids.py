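"""Voxel-grid container and NIfTI-1 I/O.

A :class:`VoxelGrid` is the universal carrier for 3-D scalar fields in this
package: ground-truth phantoms, noise fields, effect-size maps and statistic
maps.  Coordinates are 0-based voxel indices; the world affine is diagonal in
the voxel size with the origin at the grid corner.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

__all__ = ["VoxelGrid", "TissueMasks"]


@dataclass
class VoxelGrid:
    """A 3-D scalar field with physical voxel dimensions.

    Parameters
    ----------
    values : ndarray
        3-D array of finite floats, one scalar per voxel.
    voxel_size : tuple of float
        Edge lengths of a voxel in mm, all positive.
    """

    values: np.ndarray
    voxel_size: tuple[float, float, float] = (3.0, 3.0, 3.0)
    #: statistic maps may carry +/-inf sentinels (perfect model fits)
    allow_nonfinite: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError(f"values must be 3-D, got ndim={self.values.ndim}")
        if min(self.values.shape) < 1:
            raise ValueError(f"every shape component must be >= 1, got {self.values.shape}")
        self.voxel_size = tuple(float(v) for v in self.voxel_size)
        if len(self.voxel_size) != 3 or any(v <= 0 for v in self.voxel_size):
            raise ValueError(f"voxel_size components must be > 0, got {self.voxel_size}")
        if not self.allow_nonfinite and not np.all(np.isfinite(self.values)):
            raise ValueError("grid values must be finite everywhere")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def affine(self) -> np.ndarray:
        """Corner-origin diagonal affine mapping voxel indices to mm."""
        aff = np.eye(4)
        aff[0, 0], aff[1, 1], aff[2, 2] = self.voxel_size
        return aff

    def with_values(self, values: np.ndarray) -> "VoxelGrid":
        """A new grid on the same lattice with different values."""
        return VoxelGrid(values=values, voxel_size=self.voxel_size)

    def to_nifti(self, path) -> None:
        nib.save(nib.Nifti1Image(self.values.astype(np.float64), self.affine), str(path))

    @classmethod
    def from_nifti(cls, path) -> "VoxelGrid":
        img = nib.load(str(path))
        vox = tuple(float(z) for z in img.header.get_zooms()[:3])
        return cls(values=np.asanyarray(img.dataobj, dtype=float), voxel_size=vox)


@dataclass
class TissueMasks:
    """Disjoint gray-matter / white-matter / CSF boolean masks on one lattice."""

    gray: np.ndarray
    white: np.ndarray
    csf: np.ndarray

    def __post_init__(self) -> None:
        self.gray = np.asarray(self.gray, dtype=bool)
        self.white = np.asarray(self.white, dtype=bool)
        self.csf = np.asarray(self.csf, dtype=bool)
        if not (self.gray.shape == self.white.shape == self.csf.shape):
            raise ValueError("tissue masks must share one shape")
        if np.any(self.gray & self.white) or np.any(self.gray & self.csf) or np.any(self.white & self.csf):
            raise ValueError("tissue masks must be pairwise disjoint")

    @property
    def brain(self) -> np.ndarray:
        return self.gray | self.white | self.csf
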