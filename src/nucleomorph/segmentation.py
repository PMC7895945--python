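"""3D nucleus detection and segmentation.

The chain mirrors a per-plane seed detection (2D maxima with a prominence
criterion, in-plane dilation, 3D linking across z), a seeded 3D watershed on
the negated foreground probability, a two-sided size filter (small objects
removed, oversized objects re-segmented locally at a lowered threshold), and
centroid/volume extraction into a tidy per-nucleus table.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.morphology import disk, local_maxima, reconstruction
from skimage.segmentation import watershed

from .geometry import VoxelGeometry
from .images import ImageStack, LabelVolume, ProbabilityMap

logger = logging.getLogger(__name__)

__all__ = [
    "SegmentationConfig",
    "compute_foreground_probability",
    "detect_seeds",
    "watershed_segment",
    "filter_and_resegment",
    "extract_nuclei",
    "segment_stack",
]


@dataclass(frozen=True)
class SegmentationConfig:
    """Tunable thresholds of the segmentation chain.

    ``min_voxels``/``max_voxels`` default to the 1500/18,000-voxel size
    filters; the detection thresholds are deliberately exposed because they
    must be calibrated against ground truth for each imaging configuration.
    """

    foreground_threshold: float = 0.5
    seed_prominence: float = 0.1
    seed_dilation_radius: int = 2
    min_voxels: int = 1500
    max_voxels: int = 18000
    reseg_threshold_factor: float = 0.8

    def __post_init__(self) -> None:
        if not 0.0 < self.foreground_threshold < 1.0:
            raise ValueError("foreground_threshold must lie in (0, 1)")
        if not 0.0 < self.reseg_threshold_factor < 1.0:
            raise ValueError("reseg_threshold_factor must lie in (0, 1)")
        if self.min_voxels >= self.max_voxels:
            raise ValueError("min_voxels must be smaller than max_voxels")
        if self.seed_prominence <= 0:
            raise ValueError("seed_prominence must be positive")
        if self.seed_dilation_radius < 0:
            raise ValueError("seed_dilation_radius must be >= 0")


def compute_foreground_probability(
    stack: ImageStack,
    smoothing_sd_um: float = 1.0,
    background_percentile: float = 50.0,
) -> ProbabilityMap:
    """Simple intensity-based foreground probability stand-in.

    Gaussian-smooths the stack (sd given in µm, converted per axis), subtracts
    the background percentile, rescales by the 99.9th percentile of the
    residual and clips to [0, 1].  A constant stack maps to all zeros.
    """
    if smoothing_sd_um < 0:
        raise ValueError("smoothing sd must be >= 0")
    img = stack.data.astype(float)
    if smoothing_sd_um > 0:
        sigma = [smoothing_sd_um / v for v in stack.geometry.voxel_size]
        img = ndimage.gaussian_filter(img, sigma=sigma)
    bg = np.percentile(img, background_percentile)
    img = img - bg
    hi = np.percentile(img, 99.9)
    if hi <= 0:
        return ProbabilityMap(np.zeros_like(img), stack.geometry)
    return ProbabilityMap(np.clip(img / hi, 0.0, 1.0), stack.geometry)


def probability_from_array(data: np.ndarray, geometry: VoxelGeometry) -> ProbabilityMap:
    """Wrap an externally computed probability volume (values must be in [0, 1])."""
    return ProbabilityMap(np.asarray(data, dtype=float), geometry)


def _plane_maxima(plane: np.ndarray, threshold: float, prominence: float) -> np.ndarray:
    """Binary mask of 2D h-maxima (prominence >= h) with value >= threshold.

    Classical formulation: regional maxima of the grayscale reconstruction of
    ``plane − h`` under ``plane``.  Twin peaks whose mutual saddle is shallower
    than ``h`` merge into one plateau (a single seed), which is what lets the
    lowered-threshold re-detection split wrongly merged objects later.
    """
    rec = reconstruction(plane - prominence, plane, method="dilation")
    peaks = local_maxima(rec, connectivity=2)
    return peaks.astype(bool) & (plane >= threshold)


def detect_seeds(prob: ProbabilityMap, cfg: SegmentationConfig) -> LabelVolume:
    """Per-plane maxima, dilated in-plane, linked into 3D seeds across z.

    Maxima are detected independently in every z plane with prominence
    ``seed_prominence`` and value at least ``foreground_threshold``, dilated
    by an in-plane disk, and 26-connected components become one seed each.
    """
    nz = prob.geometry.shape[0]
    mask = np.zeros(prob.geometry.shape, dtype=bool)
    selem = disk(cfg.seed_dilation_radius) if cfg.seed_dilation_radius > 0 else None
    for k in range(nz):
        plane = prob.data[k]
        if plane.max() < cfg.foreground_threshold:
            continue
        m = _plane_maxima(plane, cfg.foreground_threshold, cfg.seed_prominence)
        if selem is not None and m.any():
            m = ndimage.binary_dilation(m, structure=selem)
        mask[k] = m
    labels, _ = ndimage.label(mask, structure=np.ones((3, 3, 3), dtype=int))
    return LabelVolume(labels.astype(np.int32), prob.geometry, provenance="seeds")


def watershed_segment(
    prob: ProbabilityMap, seeds: LabelVolume, cfg: SegmentationConfig
) -> LabelVolume:
    """Seeded watershed on the negated probability within the foreground mask.

    Foreground voxels unreachable from any seed stay background.  skimage's
    watershed processes equal-priority voxels in raster order, making the
    flooding deterministic.
    """
    if tuple(seeds.geometry.shape) != tuple(prob.geometry.shape):
        raise ValueError("seeds and probability map geometries differ")
    fg = prob.data >= cfg.foreground_threshold
    markers = np.where(fg, seeds.data, 0)
    if not markers.any():
        warnings.warn("no seeds inside the foreground mask; returning empty labeling")
        return LabelVolume(
            np.zeros(prob.geometry.shape, dtype=np.int32), prob.geometry, provenance="raw"
        )
    labels = watershed(-prob.data, markers=markers, mask=fg)
    return LabelVolume(labels.astype(np.int32), prob.geometry, provenance="raw")


def _relabel_consecutive(labels: np.ndarray) -> np.ndarray:
    """Relabel nonzero labels to 1..K in sorted-label order."""
    u = np.unique(labels)
    u = u[u > 0]
    lookup = np.zeros(int(labels.max()) + 1 if labels.size else 1, dtype=np.int32)
    lookup[u] = np.arange(1, len(u) + 1, dtype=np.int32)
    return lookup[labels]


def filter_and_resegment(
    labels: LabelVolume, prob: ProbabilityMap, cfg: SegmentationConfig
) -> LabelVolume:
    """Apply the two-sided size filter with local re-segmentation of merges.

    Objects below ``min_voxels`` are removed.  Objects above ``max_voxels``
    (suspected merges) are re-segmented inside their bounding box with the
    foreground threshold and seed prominence both lowered by
    ``reseg_threshold_factor``; re-segmentation products below ``min_voxels``
    are dropped.  If re-segmentation yields nothing, the original object is
    retained and flagged.  Output labels are consecutive 1..K.
    """
    lab = labels.data
    out = np.zeros_like(lab, dtype=np.int64)
    flagged: list[int] = []
    if lab.max() == 0:
        return LabelVolume(out.astype(np.int32), labels.geometry, provenance="filtered")
    counts = np.bincount(lab.ravel())
    next_label = 1
    slices = ndimage.find_objects(lab)
    low_cfg = replace(
        cfg,
        foreground_threshold=cfg.foreground_threshold * cfg.reseg_threshold_factor,
        seed_prominence=cfg.seed_prominence * cfg.reseg_threshold_factor,
    )
    for value in range(1, len(counts)):
        size = counts[value]
        if size == 0 or size < cfg.min_voxels:
            continue
        sl = slices[value - 1]
        obj_mask = lab[sl] == value
        if size <= cfg.max_voxels:
            out[sl][obj_mask] = next_label
            next_label += 1
            continue
        # oversized: local re-segmentation at the lowered threshold
        sub = np.where(obj_mask, prob.data[sl], 0.0)
        sub_geom = VoxelGeometry(sub.shape, labels.geometry.voxel_size)
        sub_prob = ProbabilityMap(sub, sub_geom)
        sub_seeds = detect_seeds(sub_prob, low_cfg)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sub_ws = watershed_segment(sub_prob, sub_seeds, low_cfg)
        parts = sub_ws.data * obj_mask
        part_counts = np.bincount(parts.ravel())
        kept = [
            v for v in range(1, len(part_counts)) if part_counts[v] >= cfg.min_voxels
        ]
        if not kept:
            logger.warning(
                "re-segmentation of oversized object %d (%d voxels) yielded no "
                "surviving parts; object retained",
                value,
                size,
            )
            flagged.append(value)
            out[sl][obj_mask] = next_label
            next_label += 1
            continue
        for v in kept:
            out[sl][parts == v] = next_label
            next_label += 1
    out = _relabel_consecutive(out)
    return LabelVolume(
        out.astype(np.int32),
        labels.geometry,
        provenance="filtered",
        flagged_labels=tuple(flagged),
    )


def extract_nuclei(
    labels: LabelVolume,
    geometry: VoxelGeometry | None = None,
    animal_id: str = "A0",
    position_id: str = "P0",
    timepoint: str | int = 0,
) -> pd.DataFrame:
    """Per-label centroid (µm) and volume (voxels and µm³) table.

    The centroid is the unweighted mean of member voxel centers in physical
    coordinates; volume is the member count times the voxel volume.
    """
    geom = geometry or labels.geometry
    lab = labels.data
    dz, dy, dx = geom.voxel_size
    idx = np.nonzero(lab)
    values = lab[idx]
    if values.size == 0:
        return pd.DataFrame(
            columns=[
                "animal_id", "position_id", "timepoint", "nucleus_id",
                "x_um", "y_um", "z_um", "volume_voxels", "volume_um3",
            ]
        )
    nmax = int(values.max())
    count = np.bincount(values, minlength=nmax + 1)
    sz = np.bincount(values, weights=idx[0], minlength=nmax + 1)
    sy = np.bincount(values, weights=idx[1], minlength=nmax + 1)
    sx = np.bincount(values, weights=idx[2], minlength=nmax + 1)
    present = np.flatnonzero(count[1:]) + 1
    n = count[present].astype(float)
    # voxel centers sit at (index + 0.5) * voxel size
    z_um = (sz[present] / n + 0.5) * dz
    y_um = (sy[present] / n + 0.5) * dy
    x_um = (sx[present] / n + 0.5) * dx
    return pd.DataFrame(
        {
            "animal_id": animal_id,
            "position_id": position_id,
            "timepoint": timepoint,
            "nucleus_id": present,
            "x_um": x_um,
            "y_um": y_um,
            "z_um": z_um,
            "volume_voxels": count[present],
            "volume_um3": count[present] * (dx * dy * dz),
        }
    )


def segment_stack(
    stack: ImageStack,
    cfg: SegmentationConfig | None = None,
    prob: ProbabilityMap | None = None,
    smoothing_sd_um: float = 1.0,
    background_percentile: float = 50.0,
    animal_id: str = "A0",
    position_id: str = "P0",
    timepoint: str | int = 0,
) -> tuple[LabelVolume, pd.DataFrame]:
    """Full chain: probability → seeds → watershed → size filter → table."""
    cfg = cfg or SegmentationConfig()
    if prob is None:
        prob = compute_foreground_probability(stack, smoothing_sd_um, background_percentile)
    seeds = detect_seeds(prob, cfg)
    raw = watershed_segment(prob, seeds, cfg)
    filtered = filter_and_resegment(raw, prob, cfg)
    table = extract_nuclei(filtered, stack.geometry, animal_id, position_id, timepoint)
    return filtered, table
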