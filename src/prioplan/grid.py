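"""Regular voxel grids.

All dose and volume accounting in this package happens on a regular,
axis-aligned voxel grid.  Conventions: 0-based voxel indices, half-open
physical extents, and mask membership decided by voxel-center inclusion,
so voxel counts translate to volumes without partial-voxel bookkeeping.
Axis order is (x, y, z) with z the cranial-caudal axis; a grid with
``nz == 1`` is the planar test mode.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True)
class VoxelGrid:
    """A regular voxel grid.

    Parameters
    ----------
    shape : tuple of int
        Number of voxels per axis ``(nx, ny, nz)``; every dim >= 1.
    spacing : tuple of float
        Voxel edge length per axis in mm; every spacing > 0.
    origin : tuple of float
        Physical coordinate (mm) of the corner of voxel ``(0, 0, 0)``.
    """

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if len(self.shape) != 3 or len(self.spacing) != 3 or len(self.origin) != 3:
            raise ValueError("shape, spacing and origin must be length-3")
        if any(int(n) < 1 for n in self.shape):
            raise ValueError(f"all grid dims must be >= 1, got {self.shape}")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"all spacings must be > 0, got {self.spacing}")
        object.__setattr__(self, "shape", tuple(int(n) for n in self.shape))
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))

    @property
    def n_voxels(self) -> int:
        nx, ny, nz = self.shape
        return nx * ny * nz

    @property
    def voxel_volume_mm3(self) -> float:
        sx, sy, sz = self.spacing
        return sx * sy * sz

    def voxel_centers(self) -> np.ndarray:
        """Physical centers of all voxels, shape ``(n_voxels, 3)`` in C order."""
        axes = [
            self.origin[a] + (np.arange(self.shape[a]) + 0.5) * self.spacing[a]
            for a in range(3)
        ]
        xx, yy, zz = np.meshgrid(*axes, indexing="ij")
        return np.column_stack([xx.ravel(), yy.ravel(), zz.ravel()])

    def axis_centers(self, axis: int) -> np.ndarray:
        return self.origin[axis] + (np.arange(self.shape[axis]) + 0.5) * self.spacing[axis]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, VoxelGrid):
            return NotImplemented
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing)
            and np.allclose(self.origin, other.origin)
        )

    def __hash__(self) -> int:
        return hash((self.shape, self.spacing, self.origin))
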