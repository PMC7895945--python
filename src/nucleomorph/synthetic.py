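"""Ground-truth phantom generation.

Generates longitudinal nucleus fields with layered density and a two-component
size mixture, renders them into two-photon-like 16-bit image stacks (depth
attenuation, vessel shadows, laser blankouts, additive noise), and builds
MRI-like baseline/follow-up phantom pairs with known deformation fields.
Everything is reproducible from an integer seed.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter, map_coordinates

from .errors import PackingError
from .geometry import VoxelGeometry
from .images import ImageStack
from .mri import DeformationField

__all__ = [
    "SizeMixture",
    "GroundTruthField",
    "LongitudinalPreset",
    "VesselCylinder",
    "ImagingModel",
    "layered_profile",
    "generate_nucleus_field",
    "select_fiducials",
    "apply_longitudinal_preset",
    "render_stack",
    "generate_mri_phantom",
    "affine_deformation",
]


@dataclass(frozen=True)
class SizeMixture:
    """Two-component lognormal nucleus-volume mixture (µm³).

    Defaults: small-nucleus (glial) component with median 600 µm³ and a larger
    (neuronal) component with median 1450 µm³ at fraction 0.55, with modest
    log-scale spreads; the resulting mixture mean is ≈ 1.1e3 µm³.
    """

    glia_median_um3: float = 600.0
    neuron_median_um3: float = 1450.0
    glia_sigma: float = 0.35
    neuron_sigma: float = 0.20
    neuron_fraction: float = 0.55

    def __post_init__(self) -> None:
        if not 0.0 <= self.neuron_fraction <= 1.0:
            raise ValueError("neuron_fraction must lie in [0, 1]")
        if self.glia_median_um3 <= 0 or self.neuron_median_um3 <= 0:
            raise ValueError("component medians must be positive")

    @property
    def mean_um3(self) -> float:
        """Analytic mixture mean."""
        mg = self.glia_median_um3 * math.exp(self.glia_sigma**2 / 2)
        mn = self.neuron_median_um3 * math.exp(self.neuron_sigma**2 / 2)
        return (1 - self.neuron_fraction) * mg + self.neuron_fraction * mn

    def sample(
        self, n: int, rng: np.random.Generator, neuron_fraction: float | None = None
    ) -> tuple[np.ndarray, np.ndarray]:
        """Draw ``n`` (class, volume_um3) pairs."""
        frac = self.neuron_fraction if neuron_fraction is None else neuron_fraction
        is_neuron = rng.random(n) < frac
        volumes = np.where(
            is_neuron,
            self.neuron_median_um3 * np.exp(rng.normal(0, self.neuron_sigma, n)),
            self.glia_median_um3 * np.exp(rng.normal(0, self.glia_sigma, n)),
        )
        classes = np.where(is_neuron, "neuron", "glia")
        return classes, volumes


def volume_to_radius_um(volume_um3: np.ndarray) -> np.ndarray:
    """Radius of the sphere with the given volume."""
    return np.cbrt(3.0 * np.asarray(volume_um3) / (4.0 * math.pi))


def layered_profile(
    base_intensity_per_um3: float,
    sparse_depth_um: float = 100.0,
    sparse_factor: float = 0.35,
) -> Callable[[np.ndarray], np.ndarray]:
    """Depth-dependent intensity: sparse superficial band, full density below."""

    def profile(z_um: np.ndarray) -> np.ndarray:
        z = np.asarray(z_um, dtype=float)
        return base_intensity_per_um3 * np.where(z < sparse_depth_um, sparse_factor, 1.0)

    return profile


@dataclass
class GroundTruthField:
    """Known-truth nucleus field inside an axis-aligned box.

    ``centroids_um`` / ``radii_um`` columns are ordered (x, y, z);
    ``extent_um`` is the (ex, ey, ez) box with the origin at (0, 0, 0).
    """

    ids: np.ndarray
    centroids_um: np.ndarray  # (n, 3) x, y, z
    radii_um: np.ndarray  # (n, 3) rx, ry, rz
    peaks: np.ndarray  # (n,) peak intensity, ADU
    classes: np.ndarray  # (n,) "glia" | "neuron"
    extent_um: tuple[float, float, float]  # (ex, ey, ez)
    fiducial_ids: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    min_separation_um: float = 0.0
    seed: int | None = None
    preset: str = "baseline"

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids, dtype=int)
        self.centroids_um = np.asarray(self.centroids_um, dtype=float).reshape(-1, 3)
        self.radii_um = np.asarray(self.radii_um, dtype=float).reshape(-1, 3)
        self.peaks = np.asarray(self.peaks, dtype=float)
        self.classes = np.asarray(self.classes)
        self.fiducial_ids = np.asarray(self.fiducial_ids, dtype=int)
        self.extent_um = tuple(float(e) for e in self.extent_um)

    @property
    def n(self) -> int:
        return len(self.ids)

    @property
    def volumes_um3(self) -> np.ndarray:
        return 4.0 / 3.0 * math.pi * np.prod(self.radii_um, axis=1)

    def validate(self) -> None:
        ext = np.asarray(self.extent_um)
        if self.n and (
            np.any(self.centroids_um < 0) or np.any(self.centroids_um > ext)
        ):
            raise ValueError("centroids fall outside the field extent")
        if len(np.unique(self.ids)) != self.n:
            raise ValueError("nucleus ids are not unique")
        if not np.isin(self.fiducial_ids, self.ids).all():
            raise ValueError("fiducial_ids must be a subset of nucleus ids")
        if self.min_separation_um > 0 and self.n > 1:
            from scipy.spatial import cKDTree

            d, _ = cKDTree(self.centroids_um).query(self.centroids_um, k=2)
            if d[:, 1].min() < self.min_separation_um - 1e-9:
                raise ValueError("hard-core separation violated")

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "nucleus_id": self.ids,
                "x_um": self.centroids_um[:, 0],
                "y_um": self.centroids_um[:, 1],
                "z_um": self.centroids_um[:, 2],
                "rx_um": self.radii_um[:, 0],
                "ry_um": self.radii_um[:, 1],
                "rz_um": self.radii_um[:, 2],
                "volume_um3": self.volumes_um3,
                "peak": self.peaks,
                "cell_class": self.classes,
                "is_fiducial": np.isin(self.ids, self.fiducial_ids),
            }
        )

    def fiducial_table(self) -> pd.DataFrame:
        df = self.to_dataframe()
        return df[df["is_fiducial"]][["nucleus_id", "x_um", "y_um", "z_um"]].rename(
            columns={"nucleus_id": "fiducial_id"}
        ).reset_index(drop=True)


class _CellHash:
    """Uniform spatial hash for O(1) hard-core neighbor queries."""

    def __init__(self, cell_um: float) -> None:
        self.cell = cell_um
        self.table: dict[tuple[int, int, int], list[np.ndarray]] = {}

    def _key(self, p: np.ndarray) -> tuple[int, int, int]:
        return tuple((p // self.cell).astype(int))

    def ok(self, p: np.ndarray, min_sep: float) -> bool:
        kx, ky, kz = self._key(p)
        for ix in range(kx - 1, kx + 2):
            for iy in range(ky - 1, ky + 2):
                for iz in range(kz - 1, kz + 2):
                    for q in self.table.get((ix, iy, iz), ()):
                        if np.sum((p - q) ** 2) < min_sep * min_sep:
                            return False
        return True

    def add(self, p: np.ndarray) -> None:
        self.table.setdefault(self._key(p), []).append(p)


def generate_nucleus_field(
    geometry: VoxelGeometry,
    layer_profile: Callable[[np.ndarray], np.ndarray],
    size_mixture: SizeMixture | None = None,
    min_separation_um: float = 4.0,
    seed: int = 0,
    peak_adu: float = 8000.0,
    max_attempt_factor: int = 200,
) -> GroundTruthField:
    """Draw a hard-core inhomogeneous-Poisson nucleus field.

    The total count is Poisson with mean ``∬ λ(z) dV``; depths follow the
    per-depth intensity ``layer_profile`` (units 1/µm³), x/y are uniform.
    Positions are placed by dart throwing against a hard-core radius of
    ``min_separation_um``; a :class:`PackingError` is raised if the target
    count cannot be placed within ``max_attempt_factor × count`` attempts.
    """
    if min_separation_um < 0:
        raise ValueError("min_separation_um must be >= 0")
    mixture = size_mixture or SizeMixture()
    rng = np.random.default_rng(seed)
    ez, ey, ex = geometry.extent_um
    # piecewise-constant depth sampling on ~1 µm bins: bands where the profile
    # is zero receive exactly zero mass (no interpolation bleed across edges)
    n_bins = max(int(round(ez)), 1)
    edges = np.linspace(0.0, ez, n_bins + 1)
    lam = np.asarray(layer_profile((edges[:-1] + edges[1:]) / 2.0), dtype=float)
    if np.any(lam < 0):
        raise ValueError("layer profile must be non-negative")
    masses = lam * np.diff(edges)
    total = float(masses.sum()) * ex * ey
    n_target = int(rng.poisson(total))
    if masses.sum() <= 0 and n_target > 0:
        raise ValueError("layer profile integrates to zero but target count > 0")
    pmass = masses / masses.sum() if masses.sum() > 0 else masses

    accepted = np.empty((n_target, 3), dtype=float)
    grid = _CellHash(max(min_separation_um, 1e-6))
    n_acc = 0
    attempts = 0
    max_attempts = max_attempt_factor * max(n_target, 1) + 1000
    while n_acc < n_target:
        batch = max(n_target - n_acc, 64)
        if attempts + batch > max_attempts:
            batch = max_attempts - attempts
            if batch <= 0:
                raise PackingError(
                    f"placed only {n_acc}/{n_target} nuclei after {attempts} attempts; "
                    "density unachievable at the requested hard-core separation"
                )
        attempts += batch
        bins = rng.choice(n_bins, size=batch, p=pmass)
        z = edges[bins] + rng.random(batch) * np.diff(edges)[bins]
        x = rng.random(batch) * ex
        y = rng.random(batch) * ey
        for p in np.stack([x, y, z], axis=1):
            if n_acc == n_target:
                break
            if min_separation_um == 0 or grid.ok(p, min_separation_um):
                accepted[n_acc] = p
                n_acc += 1
                if min_separation_um > 0:
                    grid.add(p)

    classes, volumes = mixture.sample(n_target, rng)
    r = volume_to_radius_um(volumes)
    field_ = GroundTruthField(
        ids=np.arange(1, n_target + 1),
        centroids_um=accepted,
        radii_um=np.stack([r, r, r], axis=1),
        peaks=np.full(n_target, float(peak_adu)),
        classes=classes,
        extent_um=(ex, ey, ez),
        min_separation_um=min_separation_um,
        seed=seed,
    )
    field_.validate()
    return field_


def select_fiducials(field_: GroundTruthField, n: int, seed: int = 0) -> GroundTruthField:
    """Designate ``n`` randomly chosen nuclei as stable fiducial markers."""
    if n > field_.n:
        raise ValueError(f"cannot select {n} fiducials from {field_.n} nuclei")
    rng = np.random.default_rng(seed)
    chosen = rng.choice(field_.ids, size=n, replace=False)
    return replace(field_, fiducial_ids=np.sort(chosen))


@dataclass(frozen=True)
class LongitudinalPreset:
    """Ground-truth tissue change between two timepoints."""

    volume_change_fraction: float = 0.0  # e.g. -0.05 for 5% shrinkage
    cell_loss_probability: float = 0.0
    cell_gain_rate_per_um3: float = 0.0
    nucleus_volume_scale: float = 1.0
    composition_shift: float = 0.0  # added to the neuron fraction for gained cells
    fiducial_noise_sd_um: float = 0.0  # re-localization noise, per axis

    def __post_init__(self) -> None:
        if self.volume_change_fraction <= -1.0:
            raise ValueError("volume_change_fraction must be > -1")
        if not 0.0 <= self.cell_loss_probability <= 1.0:
            raise ValueError("cell_loss_probability must lie in [0, 1]")
        if self.cell_gain_rate_per_um3 < 0:
            raise ValueError("cell_gain_rate_per_um3 must be >= 0")
        if self.nucleus_volume_scale <= 0:
            raise ValueError("nucleus_volume_scale must be positive")
        if self.fiducial_noise_sd_um < 0:
            raise ValueError("fiducial_noise_sd_um must be >= 0")


def apply_longitudinal_preset(
    field_: GroundTruthField,
    preset: LongitudinalPreset,
    seed: int = 0,
    size_mixture: SizeMixture | None = None,
    preset_name: str = "follow-up",
) -> tuple[GroundTruthField, pd.DataFrame]:
    """Evolve a field by one longitudinal interval.

    Coordinates are mapped by the isotropic affine with per-axis scale
    ``(1 + volume_change_fraction)^(1/3)`` about the extent center; survivors
    are Bernoulli draws, gained cells are appended with fresh ids, nucleus
    volumes are rescaled, and surviving fiducial coordinates receive Gaussian
    re-localization noise.  Returns the new field and a survivor
    correspondence table (old_id → new_id).
    """
    rng = np.random.default_rng(seed)
    mixture = size_mixture or SizeMixture()
    ext = np.asarray(field_.extent_um)
    center = ext / 2.0
    scale = (1.0 + preset.volume_change_fraction) ** (1.0 / 3.0)
    coords = center + scale * (field_.centroids_um - center)

    survive = rng.random(field_.n) >= preset.cell_loss_probability
    ids = field_.ids[survive]
    coords = coords[survive]
    radii = field_.radii_um[survive] * preset.nucleus_volume_scale ** (1.0 / 3.0)
    peaks = field_.peaks[survive]
    classes = field_.classes[survive]

    # re-localization noise on surviving fiducials only
    fiducial_ids = field_.fiducial_ids[np.isin(field_.fiducial_ids, ids)]
    if preset.fiducial_noise_sd_um > 0 and len(fiducial_ids):
        mask = np.isin(ids, fiducial_ids)
        coords = coords.copy()
        coords[mask] += rng.normal(0.0, preset.fiducial_noise_sd_um, (mask.sum(), 3))
        coords = np.clip(coords, 0.0, ext)

    n_gain = int(rng.poisson(preset.cell_gain_rate_per_um3 * float(np.prod(ext))))
    if n_gain:
        frac = min(max(mixture.neuron_fraction + preset.composition_shift, 0.0), 1.0)
        g_classes, g_volumes = mixture.sample(n_gain, rng, neuron_fraction=frac)
        g_r = volume_to_radius_um(g_volumes * preset.nucleus_volume_scale)
        g_coords = rng.random((n_gain, 3)) * ext
        next_id = int(field_.ids.max()) + 1 if field_.n else 1
        g_ids = np.arange(next_id, next_id + n_gain)
        ids = np.concatenate([ids, g_ids])
        coords = np.vstack([coords, g_coords])
        radii = np.vstack([radii, np.stack([g_r, g_r, g_r], axis=1)])
        peaks = np.concatenate([peaks, np.full(n_gain, float(np.median(field_.peaks)) if field_.n else 8000.0)])
        classes = np.concatenate([classes, g_classes])

    out = GroundTruthField(
        ids=ids,
        centroids_um=coords,
        radii_um=radii,
        peaks=peaks,
        classes=classes,
        extent_um=field_.extent_um,
        fiducial_ids=fiducial_ids,
        min_separation_um=0.0,  # scaling/jitter may tighten pair distances
        seed=seed,
        preset=preset_name,
    )
    out.validate()
    correspondence = pd.DataFrame(
        {"old_id": field_.ids[survive], "new_id": field_.ids[survive]}
    )
    return out, correspondence


@dataclass(frozen=True)
class VesselCylinder:
    """Infinite cylinder casting a full shadow; point/direction in (x, y, z) µm."""

    point_um: tuple[float, float, float]
    direction: tuple[float, float, float]
    radius_um: float

    def __post_init__(self) -> None:
        d = np.asarray(self.direction, dtype=float)
        norm = np.linalg.norm(d)
        if norm == 0:
            raise ValueError("direction must be nonzero")
        if self.radius_um <= 0:
            raise ValueError("radius must be positive")
        object.__setattr__(self, "direction", tuple(d / norm))


@dataclass(frozen=True)
class ImagingModel:
    """Two-photon image-formation parameters."""

    attenuation_length_um: float = 300.0  # depth decay exp(-z/L)
    background_offset: float = 100.0  # ADU
    noise_sd: float = 20.0  # additive Gaussian, ADU
    vessels: tuple = ()
    blankout_planes: tuple = ()  # (start, stop) half-open z-plane ranges

    def __post_init__(self) -> None:
        if self.attenuation_length_um <= 0:
            raise ValueError("attenuation length must be > 0")
        if self.background_offset < 0 or self.noise_sd < 0:
            raise ValueError("offset and noise sd must be >= 0")


def render_stack(
    field_: GroundTruthField,
    geometry: VoxelGeometry,
    imaging: ImagingModel,
    seed: int = 0,
) -> ImageStack:
    """Render nuclei as anisotropic Gaussian blobs into a 16-bit stack.

    Per-axis blob sd is half the nucleus radius; peaks decay as
    ``exp(-z/L)``; vessel interiors carry offset only; blankout planes are
    zeroed before additive Gaussian noise and clipping to [0, 65535].
    """
    ez, ey, ex = geometry.extent_um
    fx, fy, fz = field_.extent_um
    if fx > ex + 1e-6 or fy > ey + 1e-6 or fz > ez + 1e-6:
        raise ValueError("field extent does not fit the rendering geometry")
    rng = np.random.default_rng(seed)
    nz, ny, nx = geometry.shape
    dz, dy, dx = geometry.voxel_size
    sig = np.zeros((nz, ny, nx), dtype=float)

    for i in range(field_.n):
        x, y, z = field_.centroids_um[i]
        rx, ry, rz = field_.radii_um[i]
        peak = field_.peaks[i] * math.exp(-z / imaging.attenuation_length_um)
        ci = geometry.um_to_index(np.array([z, y, x]))  # fractional (z, y, x) index
        if rx < dx or ry < dy or rz < dz:
            warnings.warn(
                f"nucleus {field_.ids[i]} radius below one voxel; rendered as a single voxel",
                stacklevel=2,
            )
            iz, iy, ix = np.clip(
                np.round(ci).astype(int), 0, np.array([nz - 1, ny - 1, nx - 1])
            )
            sig[iz, iy, ix] += peak
            continue
        sz, sy, sx = rz / 2.0 / dz, ry / 2.0 / dy, rx / 2.0 / dx  # sd in voxels
        z0, z1 = int(max(0, math.floor(ci[0] - 4 * sz))), int(min(nz, math.ceil(ci[0] + 4 * sz) + 1))
        y0, y1 = int(max(0, math.floor(ci[1] - 4 * sy))), int(min(ny, math.ceil(ci[1] + 4 * sy) + 1))
        x0, x1 = int(max(0, math.floor(ci[2] - 4 * sx))), int(min(nx, math.ceil(ci[2] + 4 * sx) + 1))
        if z0 >= z1 or y0 >= y1 or x0 >= x1:
            continue
        zz = (np.arange(z0, z1) - ci[0]) / sz
        yy = (np.arange(y0, y1) - ci[1]) / sy
        xx = (np.arange(x0, x1) - ci[2]) / sx
        blob = np.exp(
            -0.5
            * (
                zz[:, None, None] ** 2
                + yy[None, :, None] ** 2
                + xx[None, None, :] ** 2
            )
        )
        sig[z0:z1, y0:y1, x0:x1] += peak * blob

    if imaging.vessels:
        zc, yc, xc = geometry.center_grids_um()
        for vessel in imaging.vessels:
            px, py, pz = vessel.point_um
            ux, uy, uz = vessel.direction
            vx, vy, vz = xc - px, yc - py, zc - pz
            t = vx * ux + vy * uy + vz * uz
            d2 = vx * vx + vy * vy + vz * vz - t * t
            sig[d2 < vessel.radius_um**2] = 0.0

    img = sig + imaging.background_offset
    for start, stop in imaging.blankout_planes:
        img[int(start) : int(stop)] = 0.0
    if imaging.noise_sd > 0:
        img = img + rng.normal(0.0, imaging.noise_sd, img.shape)
    img = np.clip(np.round(img), 0, 65535).astype(np.uint16)
    return ImageStack(img, geometry)


def affine_deformation(
    scale: float | Sequence[float], offset_um: Sequence[float] = (0.0, 0.0, 0.0)
) -> tuple[np.ndarray, np.ndarray]:
    """Convenience (A, b) pair for ``φ(v) = A·v + b`` with per-axis (z, y, x) scale."""
    s = np.broadcast_to(np.asarray(scale, dtype=float), (3,))
    return np.diag(s), np.asarray(offset_um, dtype=float)


def generate_mri_phantom(
    deformation,
    mri_geometry: VoxelGeometry,
    noise_sd: float = 0.0,
    seed: int = 0,
    baseline: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, DeformationField]:
    """Build a baseline/follow-up MRI-like volume pair with a known deformation.

    ``deformation`` is either an ``(A, b)`` affine pair or a callable mapping
    physical (z, y, x) µm coordinates (..., 3) to *source* coordinates (the
    baseline location each follow-up voxel samples from).  The stored
    displacement is ``φ(v) − v`` in µm.  Source positions falling outside the
    baseline domain raise a ``ValueError``.
    """
    rng = np.random.default_rng(seed)
    shape = mri_geometry.shape
    if baseline is None:
        baseline = 600.0 + 120.0 * gaussian_filter(rng.standard_normal(shape), sigma=2.0)
    baseline = np.asarray(baseline, dtype=float)
    if tuple(baseline.shape) != tuple(shape):
        raise ValueError("baseline shape does not match MRI geometry")

    zc, yc, xc = mri_geometry.center_grids_um()
    grid = np.stack(np.broadcast_arrays(zc, yc, xc), axis=-1)  # (nz, ny, nx, 3)
    if callable(deformation):
        source = np.asarray(deformation(grid), dtype=float)
        if source.shape != grid.shape:
            raise ValueError("deformation callable must return (..., 3) source coords")
    else:
        A, b = deformation
        A = np.asarray(A, dtype=float).reshape(3, 3)
        b = np.asarray(b, dtype=float).reshape(3)
        source = grid @ A.T + b

    extent = np.asarray(mri_geometry.extent_um)
    slack = 0.5 * np.asarray(mri_geometry.voxel_size)
    if np.any(source < -slack) or np.any(source > extent + slack):
        raise ValueError("deformation displaces voxels outside the image domain")

    idx = mri_geometry.um_to_index(source)  # fractional (z, y, x) indices
    followup = map_coordinates(
        baseline, [idx[..., 0], idx[..., 1], idx[..., 2]], order=3, mode="nearest"
    )
    if noise_sd > 0:
        followup = followup + rng.normal(0.0, noise_sd, followup.shape)
    disp = DeformationField(source - grid, mri_geometry)
    return baseline, followup, disp
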