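"""Voxel-grid geometry shared by all imaging modules.

Arrays are stored in (z, y, x) order.  The physical origin sits at the corner
of voxel (0, 0, 0); z increases with depth and z = 0 is the tissue surface.
Voxel *centers* therefore lie at ``(index + 0.5) * voxel_size``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class VoxelGeometry:
    """Shape and voxel spacing of a 3D image grid.

    Parameters
    ----------
    shape
        ``(nz, ny, nx)`` number of voxels per axis.
    voxel_size
        ``(dz, dy, dx)`` voxel edge lengths in µm.
    """

    shape: tuple[int, int, int]
    voxel_size: tuple[float, float, float]

    def __post_init__(self) -> None:
        shape = tuple(int(s) for s in self.shape)
        size = tuple(float(v) for v in self.voxel_size)
        if len(shape) != 3 or len(size) != 3:
            raise ValueError("shape and voxel_size must have 3 entries (z, y, x)")
        if any(s < 1 for s in shape):
            raise ValueError(f"all shape entries must be >= 1, got {shape}")
        if any(v <= 0 for v in size):
            raise ValueError(f"all voxel sizes must be > 0, got {size}")
        object.__setattr__(self, "shape", shape)
        object.__setattr__(self, "voxel_size", size)

    @property
    def extent_um(self) -> tuple[float, float, float]:
        """Physical extent ``(ez, ey, ex)`` in µm (shape × voxel size)."""
        return tuple(s * v for s, v in zip(self.shape, self.voxel_size))

    @property
    def voxel_volume_um3(self) -> float:
        dz, dy, dx = self.voxel_size
        return dz * dy * dx

    def index_to_um(self, index: np.ndarray) -> np.ndarray:
        """Map (fractional) voxel indices (..., 3; z,y,x) to physical voxel-center µm."""
        return (np.asarray(index, dtype=float) + 0.5) * np.asarray(self.voxel_size)

    def um_to_index(self, pos_um: np.ndarray) -> np.ndarray:
        """Map physical µm coordinates (..., 3; z,y,x) to fractional voxel indices."""
        return np.asarray(pos_um, dtype=float) / np.asarray(self.voxel_size) - 0.5

    def center_grids_um(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Broadcastable 1D arrays of voxel-center coordinates per axis (z, y, x) in µm."""
        nz, ny, nx = self.shape
        dz, dy, dx = self.voxel_size
        z = (np.arange(nz) + 0.5) * dz
        y = (np.arange(ny) + 0.5) * dy
        x = (np.arange(nx) + 0.5) * dx
        return z.reshape(-1, 1, 1), y.reshape(1, -1, 1), x.reshape(1, 1, -1)
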