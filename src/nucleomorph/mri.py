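"""MRI-space operations.

Cross-modal mask construction from in-plane vessel fiducials, per-voxel
Jacobian-determinant extraction from displacement fields, mask-restricted
volume-change readout, and fast-spin-echo acquisition arithmetic.

Conventions: MRI volumes are stored (z, y, x) with physical coordinates in µm
(voxel centers at ``(i + 0.5) * voxel_size``); displacement fields carry a
trailing component axis ordered (z, y, x) in µm and follow the pull-back
convention — the displacement maps a follow-up grid location to the baseline
location the sample came from, so the determinant of ``I + ∇u`` is the local
baseline/follow-up volume ratio.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import DegenerateGeometryError, NucleomorphError
from .geometry import VoxelGeometry


@dataclass(frozen=True)
class AffineTransform2D:
    """2D affine map from two-photon XY (µm) to MRI in-plane coordinates (µm)."""

    matrix: tuple  # 2x2 linear part, row-major
    translation: tuple  # length-2

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float).reshape(2, 2)
        t = np.asarray(self.translation, dtype=float).reshape(2)
        if abs(np.linalg.det(m)) <= 1e-12:
            raise DegenerateGeometryError("affine linear part is singular")
        object.__setattr__(self, "matrix", tuple(map(tuple, m)))
        object.__setattr__(self, "translation", tuple(t))

    @property
    def A(self) -> np.ndarray:
        return np.asarray(self.matrix, dtype=float)

    @property
    def b(self) -> np.ndarray:
        return np.asarray(self.translation, dtype=float)

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        return pts @ self.A.T + self.b

    def inverse(self) -> "AffineTransform2D":
        Ainv = np.linalg.inv(self.A)
        return AffineTransform2D(tuple(map(tuple, Ainv)), tuple(-Ainv @ self.b))


@dataclass(frozen=True)
class AffineFit:
    """Result of fitting an in-plane affine to corresponding point pairs."""

    transform: AffineTransform2D
    residuals_um: np.ndarray  # (n, 2) dst - transform(src)

    @property
    def rms_um(self) -> float:
        return float(np.sqrt(np.mean(np.sum(self.residuals_um**2, axis=1))))


def fit_affine_xy(source_xy: np.ndarray, target_xy: np.ndarray) -> AffineFit:
    """Fit the 2D affine mapping ``source_xy`` onto ``target_xy``.

    Exactly three non-collinear pairs give the interpolating affine (zero
    residuals); more pairs are fit by least squares.
    """
    src = np.atleast_2d(np.asarray(source_xy, dtype=float))
    dst = np.atleast_2d(np.asarray(target_xy, dtype=float))
    if src.shape != dst.shape or src.shape[1] != 2:
        raise ValueError("source and target must be matching (n, 2) arrays")
    if len(src) < 3:
        raise ValueError("at least 3 point pairs are required")
    centered = src - src.mean(axis=0)
    # collinearity <=> zero area spanned by centered sources
    if np.linalg.matrix_rank(centered, tol=1e-9 * max(1.0, np.abs(src).max())) < 2:
        raise DegenerateGeometryError("source points are collinear")
    design = np.hstack([src, np.ones((len(src), 1))])
    params, *_ = np.linalg.lstsq(design, dst, rcond=None)
    A = params[:2].T
    b = params[2]
    transform = AffineTransform2D(tuple(map(tuple, A)), tuple(b))
    residuals = dst - transform.apply(src)
    return AffineFit(transform, residuals)


@dataclass
class MaskVolume:
    """Binary stack footprint on the MRI grid, confined to consecutive z planes."""

    data: np.ndarray
    geometry: VoxelGeometry
    surface_plane: int
    n_planes: int

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=bool)
        if tuple(self.data.shape) != tuple(self.geometry.shape):
            raise ValueError("mask shape does not match geometry")
        if not self.data.any():
            raise ValueError("mask is empty")
        occupied = np.flatnonzero(self.data.any(axis=(1, 2)))
        expected = np.arange(self.surface_plane, self.surface_plane + self.n_planes)
        if not np.array_equal(occupied, expected):
            raise ValueError(
                f"occupied z planes {occupied.tolist()} are not the {self.n_planes} "
                f"consecutive planes starting at {self.surface_plane}"
            )


def rasterize_stack_mask(
    transform: AffineTransform2D,
    stack_extent_xy_um: float,
    mri_geometry: VoxelGeometry,
    surface_plane: int,
    n_planes: int = 3,
) -> MaskVolume:
    """Rasterize the square two-photon footprint into a binary MRI mask.

    An MRI voxel is included in-plane iff its center lies inside the affine
    image of the ``[0, L]²`` stack footprint; in depth the mask occupies
    ``n_planes`` consecutive planes starting at ``surface_plane``.
    """
    if stack_extent_xy_um <= 0:
        raise ValueError("stack extent must be positive")
    nz, ny, nx = mri_geometry.shape
    if not (0 <= surface_plane and surface_plane + n_planes <= nz):
        raise ValueError("requested z planes fall outside the MRI grid")
    dz, dy, dx = mri_geometry.voxel_size
    # voxel centers, in-plane
    xc = (np.arange(nx) + 0.5) * dx
    yc = (np.arange(ny) + 0.5) * dy
    X, Y = np.meshgrid(xc, yc)  # (ny, nx)
    centers = np.stack([X.ravel(), Y.ravel()], axis=1)
    # inverse-map centers into the stack frame; inside iff within [0, L]^2
    inv = transform.inverse()
    uv = inv.apply(centers)
    L = float(stack_extent_xy_um)
    inside = (
        (uv[:, 0] >= 0.0) & (uv[:, 0] <= L) & (uv[:, 1] >= 0.0) & (uv[:, 1] <= L)
    ).reshape(ny, nx)
    if not inside.any():
        raise NucleomorphError("transformed footprint does not cover any voxel center")
    mask = np.zeros((nz, ny, nx), dtype=bool)
    mask[surface_plane : surface_plane + n_planes] = inside
    return MaskVolume(mask, mri_geometry, surface_plane, n_planes)


@dataclass
class DeformationField:
    """Per-voxel displacement in µm on an MRI grid; components ordered (z, y, x)."""

    displacement_um: np.ndarray  # (nz, ny, nx, 3)
    geometry: VoxelGeometry

    def __post_init__(self) -> None:
        self.displacement_um = np.asarray(self.displacement_um, dtype=float)
        if self.displacement_um.ndim != 4 or self.displacement_um.shape[-1] != 3:
            raise ValueError("displacement must have shape (nz, ny, nx, 3)")
        if tuple(self.displacement_um.shape[:3]) != tuple(self.geometry.shape):
            raise ValueError("displacement grid does not match geometry")


@dataclass
class JacobianField:
    """Per-voxel determinant of the deformation gradient (dimensionless)."""

    determinant: np.ndarray
    geometry: VoxelGeometry
    n_nonpositive: int = 0

    @property
    def all_positive(self) -> bool:
        return self.n_nonpositive == 0


def jacobian_determinant_field(field: DeformationField) -> JacobianField:
    """Determinant of ``I + ∇u`` via central differences (one-sided at borders).

    Central differences are exact on affine displacement fields, so a uniform
    per-axis scale ``s`` yields ``s³`` everywhere.
    """
    u = field.displacement_um
    if not np.all(np.isfinite(u)):
        raise ValueError("displacement field contains non-finite values")
    if any(s < 3 for s in field.geometry.shape):
        raise ValueError("grid must have at least 3 voxels per axis")
    dz, dy, dx = field.geometry.voxel_size
    # grad[c][k] = d u_c / d axis_k  (axes ordered z, y, x)
    grad = np.empty(field.geometry.shape + (3, 3), dtype=float)
    for c in range(3):
        gz, gy, gx = np.gradient(u[..., c], dz, dy, dx, edge_order=1)
        grad[..., c, 0] = gz
        grad[..., c, 1] = gy
        grad[..., c, 2] = gx
    F = grad + np.eye(3)
    det = np.linalg.det(F)
    n_nonpos = int(np.count_nonzero(det <= 0))
    return JacobianField(det, field.geometry, n_nonpos)


@dataclass(frozen=True)
class GmvChange:
    """Mask-restricted volume-change readout."""

    percent_of_baseline: float
    slice_profile: np.ndarray  # per-occupied-plane mean determinant (percent)
    plane_indices: np.ndarray


def gmv_change_in_mask(jfield: JacobianField, mask: MaskVolume) -> GmvChange:
    """Percent-of-baseline volume inside the mask plus a slicewise profile.

    Percent is 100 × the mean Jacobian determinant over mask voxels; the
    profile holds the per-z-plane mean over each occupied mask plane.
    """
    if tuple(jfield.determinant.shape) != tuple(mask.data.shape):
        raise ValueError("Jacobian field and mask geometries differ")
    if not mask.data.any():
        raise ValueError("mask is empty")
    det = jfield.determinant
    percent = 100.0 * float(det[mask.data].mean())
    planes = np.flatnonzero(mask.data.any(axis=(1, 2)))
    profile = np.array(
        [100.0 * float(det[k][mask.data[k]].mean()) for k in planes], dtype=float
    )
    return GmvChange(percent, profile, planes)


@dataclass(frozen=True)
class AcquisitionParams:
    """Fast-spin-echo acquisition parameters (times in ms unless noted)."""

    te_ms: float
    tr_s: float
    rare_factor: int
    echo_spacing_ms: float
    t2_ms: float

    def __post_init__(self) -> None:
        for name in ("te_ms", "tr_s", "echo_spacing_ms", "t2_ms"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if int(self.rare_factor) < 1:
            raise ValueError("rare_factor must be a positive integer")

    @property
    def trajectory_time_ms(self) -> float:
        """Echo-train trajectory time: RARE factor × echo spacing."""
        return self.rare_factor * self.echo_spacing_ms


def psf_blurring_factor(acq: AcquisitionParams) -> float:
    """FWHM inflation of the point spread function from truncation + T2 decay.

    Evaluates ``1.23 − 0.05·(Tk/T2) + 0.08·(Tk/T2)²`` with Tk the trajectory
    time and T2 the tissue relaxation time.
    """
    if acq.t2_ms <= 0:
        raise ValueError("T2 must be positive")
    r = acq.trajectory_time_ms / acq.t2_ms
    return 1.23 - 0.05 * r + 0.08 * r * r
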