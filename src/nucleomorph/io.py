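"""File I/O: multi-page TIFF stacks, HDF5 probability volumes, NIfTI fields, CSV tables."""

from __future__ import annotations

from pathlib import Path

import h5py
import nibabel as nib
import numpy as np
import pandas as pd
import tifffile

from .geometry import VoxelGeometry
from .images import ImageStack, LabelVolume, ProbabilityMap
from .mri import DeformationField, MaskVolume

NUCLEUS_COLUMNS = [
    "animal_id", "position_id", "timepoint", "nucleus_id",
    "x_um", "y_um", "z_um", "volume_voxels", "volume_um3",
]
FIDUCIAL_CSV_COLUMNS = [
    "animal_id", "position_id", "timepoint", "fiducial_id", "x_um", "y_um", "z_um",
]


def write_stack_tiff(path, stack: ImageStack) -> None:
    """Write a z-major multi-page 16-bit TIFF."""
    tifffile.imwrite(str(path), stack.data.astype(np.uint16))


def read_stack_tiff(path, voxel_size_um=(2.0, 0.29, 0.29)) -> ImageStack:
    data = tifffile.imread(str(path))
    if data.ndim == 2:
        data = data[None]
    geom = VoxelGeometry(data.shape, voxel_size_um)
    return ImageStack(data, geom)


def write_labels_tiff(path, labels: LabelVolume) -> None:
    tifffile.imwrite(str(path), labels.data.astype(np.int32))


def read_labels_tiff(path, voxel_size_um=(2.0, 0.29, 0.29), provenance="filtered") -> LabelVolume:
    data = tifffile.imread(str(path)).astype(np.int32)
    if data.ndim == 2:
        data = data[None]
    geom = VoxelGeometry(data.shape, voxel_size_um)
    return LabelVolume(data, geom, provenance=provenance)


def read_probability_h5(path, dataset="exported_data", voxel_size_um=(2.0, 0.29, 0.29)) -> ProbabilityMap:
    """Read an externally produced foreground-probability volume from HDF5.

    Accepts a plain (z, y, x) volume or a (z, y, x, channel) export, in which
    case the last channel axis is reduced to its first channel.
    """
    with h5py.File(str(path), "r") as fh:
        if dataset not in fh:
            raise KeyError(f"dataset {dataset!r} not found in {path}")
        data = np.asarray(fh[dataset])
    if data.ndim == 4:
        data = data[..., 0]
    geom = VoxelGeometry(data.shape, voxel_size_um)
    return ProbabilityMap(data.astype(float), geom)


def write_probability_h5(path, prob: ProbabilityMap, dataset="exported_data") -> None:
    with h5py.File(str(path), "w") as fh:
        fh.create_dataset(dataset, data=prob.data)


def _nifti_affine(geometry: VoxelGeometry) -> np.ndarray:
    # data is stored (z, y, x); nibabel's i axis maps to z etc.
    dz, dy, dx = geometry.voxel_size
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = dz, dy, dx
    return aff


def write_volume_nifti(path, data: np.ndarray, geometry: VoxelGeometry) -> None:
    img = nib.Nifti1Image(np.asarray(data, dtype=np.float32), _nifti_affine(geometry))
    nib.save(img, str(path))


def read_volume_nifti(path) -> tuple[np.ndarray, VoxelGeometry]:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    zooms = img.header.get_zooms()[:3]
    geom = VoxelGeometry(data.shape[:3], tuple(float(z) for z in zooms))
    return data, geom


def write_deformation_nifti(path, field: DeformationField) -> None:
    """Displacement as 4D NIfTI; last axis holds (z, y, x) components in µm."""
    img = nib.Nifti1Image(
        field.displacement_um.astype(np.float32), _nifti_affine(field.geometry)
    )
    nib.save(img, str(path))


def read_deformation_nifti(path) -> DeformationField:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 4 or data.shape[-1] != 3:
        raise ValueError("deformation NIfTI must be 4D with 3 components")
    zooms = img.header.get_zooms()[:3]
    geom = VoxelGeometry(data.shape[:3], tuple(float(z) for z in zooms))
    return DeformationField(data, geom)


def write_mask_nifti(path, mask: MaskVolume) -> None:
    img = nib.Nifti1Image(mask.data.astype(np.uint8), _nifti_affine(mask.geometry))
    img.header["descrip"] = f"surface_plane={mask.surface_plane};n_planes={mask.n_planes}".encode()
    nib.save(img, str(path))


def read_mask_nifti(path) -> MaskVolume:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj).astype(bool)
    zooms = img.header.get_zooms()[:3]
    geom = VoxelGeometry(data.shape, tuple(float(z) for z in zooms))
    occupied = np.flatnonzero(data.any(axis=(1, 2)))
    return MaskVolume(data, geom, int(occupied[0]), len(occupied))


def write_nucleus_table(path, table: pd.DataFrame) -> None:
    table.to_csv(path, index=False)


def read_nucleus_table(path) -> pd.DataFrame:
    table = pd.read_csv(path)
    missing = [c for c in ("x_um", "y_um", "z_um", "volume_um3") if c not in table.columns]
    if missing:
        raise ValueError(f"nucleus CSV is missing columns {missing}")
    return table


def read_fiducial_table(path) -> pd.DataFrame:
    table = pd.read_csv(path)
    missing = [c for c in FIDUCIAL_CSV_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"fiducial CSV is missing columns {missing}")
    return table


def read_point_pairs(path) -> tuple[np.ndarray, np.ndarray]:
    """CSV with columns x2p_um, y2p_um, xmri_um, ymri_um."""
    df = pd.read_csv(path)
    cols = ["x2p_um", "y2p_um", "xmri_um", "ymri_um"]
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"point-pair CSV is missing columns {missing}")
    return df[cols[:2]].to_numpy(float), df[cols[2:]].to_numpy(float)
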