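"""Core image containers: intensity stacks, probability maps, label volumes."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import VoxelGeometry


def _check_shape(data: np.ndarray, geometry: VoxelGeometry) -> None:
    if tuple(data.shape) != tuple(geometry.shape):
        raise ValueError(
            f"array shape {data.shape} does not match geometry shape {geometry.shape}"
        )


@dataclass
class ImageStack:
    """3D intensity volume with unsigned 16-bit semantics, (z, y, x) order."""

    data: np.ndarray
    geometry: VoxelGeometry

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError("ImageStack data must be 3D (z, y, x)")
        _check_shape(self.data, self.geometry)
        if np.issubdtype(self.data.dtype, np.floating) and np.any(self.data < 0):
            raise ValueError("ImageStack values must be non-negative")


@dataclass
class ProbabilityMap:
    """3D foreground-probability volume with values in [0, 1]."""

    data: np.ndarray
    geometry: VoxelGeometry

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("ProbabilityMap data must be 3D (z, y, x)")
        _check_shape(self.data, self.geometry)
        if self.data.size and (self.data.min() < 0.0 or self.data.max() > 1.0):
            raise ValueError("probability values must lie in [0, 1]")


@dataclass
class LabelVolume:
    """3D integer labeling; 0 is background, positive labels are objects."""

    data: np.ndarray
    geometry: VoxelGeometry
    provenance: str = "raw"
    flagged_labels: tuple = field(default_factory=tuple)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError("LabelVolume data must be 3D (z, y, x)")
        if not np.issubdtype(self.data.dtype, np.integer):
            raise ValueError("LabelVolume data must be integer-typed")
        _check_shape(self.data, self.geometry)
        if self.data.size and self.data.min() < 0:
            raise ValueError("labels must be non-negative")

    @property
    def labels(self) -> np.ndarray:
        """Sorted array of nonzero labels present in the volume."""
        u = np.unique(self.data)
        return u[u > 0]
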