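"""In-memory containers for 4D BOLD series and grid geometry."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True)
class GridGeometry:
    """A regular 3D voxel grid with a voxel-to-mm (MNI-like) affine.

    Parameters
    ----------
    shape : tuple of int
        Number of voxels along x, y, z.
    affine : ndarray, shape (4, 4)
        Maps voxel indices (i, j, k, 1) to millimetre coordinates.
    """

    shape: tuple[int, int, int]
    affine: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "shape", tuple(int(s) for s in self.shape))
        aff = np.asarray(self.affine, dtype=float)
        if aff.shape != (4, 4):
            raise ValueError(f"affine must be 4x4, got {aff.shape}")
        object.__setattr__(self, "affine", aff)

    @property
    def voxel_sizes(self) -> np.ndarray:
        """Voxel edge lengths in mm along each axis."""
        return np.sqrt((self.affine[:3, :3] ** 2).sum(axis=0))

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in mm^3."""
        return float(abs(np.linalg.det(self.affine[:3, :3])))

    def voxel_to_mm(self, ijk: np.ndarray) -> np.ndarray:
        """Map voxel indices (..., 3) to mm coordinates (..., 3)."""
        ijk = np.asarray(ijk, dtype=float)
        return ijk @ self.affine[:3, :3].T + self.affine[:3, 3]

    def mm_to_voxel(self, xyz: np.ndarray) -> np.ndarray:
        """Map mm coordinates (..., 3) to (fractional) voxel indices."""
        xyz = np.asarray(xyz, dtype=float)
        inv = np.linalg.inv(self.affine)
        return (xyz - self.affine[:3, 3]) @ inv[:3, :3].T


def default_grid(shape: tuple[int, int, int] = (30, 36, 30),
                 voxel_size: float = 3.0) -> GridGeometry:
    """A small MNI-like bounding box at 3 mm isotropic resolution.

    The origin is placed so the mm coordinate (0, 0, 0) falls on a voxel
    centre inside the grid, with the inferior-medial midbrain region
    comfortably in-grid.
    """
    shape = tuple(int(s) for s in shape)
    affine = np.diag([voxel_size, voxel_size, voxel_size, 1.0])
    # centre the box around x=0 (index shape/2 maps to 0), brainstem low in z
    affine[:3, 3] = [-voxel_size * (shape[0] // 2),
                     -voxel_size * (shape[1] * 3 // 5),
                     -voxel_size * (shape[2] * 2 // 5)]
    return GridGeometry(shape=shape, affine=affine)


@dataclass
class Bold4D:
    """A 4D BOLD series on a regular grid.

    Attributes
    ----------
    data : ndarray, shape (nx, ny, nz, nt)
        Signal intensities, time along the last axis.
    affine : ndarray, shape (4, 4)
        Voxel-to-mm affine.
    tr : float
        Repetition time in seconds.
    """

    data: np.ndarray
    affine: np.ndarray
    tr: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4:
            raise ValueError(f"BOLD data must be 4D, got {self.data.ndim}D")
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4):
            raise ValueError(f"affine must be 4x4, got {self.affine.shape}")
        if not self.tr > 0:
            raise ValueError(f"TR must be positive, got {self.tr}")

    @property
    def shape3(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[3]

    @property
    def grid(self) -> GridGeometry:
        return GridGeometry(shape=self.shape3, affine=self.affine)

    def copy_with(self, data: np.ndarray) -> "Bold4D":
        """A new series sharing this one's geometry and TR."""
        return Bold4D(data=data, affine=self.affine.copy(), tr=self.tr)
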