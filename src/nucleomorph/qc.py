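"""Imaging quality control and exclusion criteria.

SNR (signal-ROI mean over background-ROI standard deviation) with a paired
stability rating, a count-scaled z-density-profile difference score acting as
an exclusion surrogate, and laser-blankout plane detection.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .images import ImageStack

__all__ = [
    "RegionOfInterest",
    "compute_snr",
    "rate_snr_stability",
    "DensityScore",
    "density_profile_score",
    "detect_blankouts",
    "QCReport",
    "build_qc_report",
]

DENSITY_SCORE_THRESHOLD = 500.0  # cells; flags a dataset for manual review


@dataclass(frozen=True)
class RegionOfInterest:
    """Axis-aligned voxel box (half-open ranges) with a signal/background role."""

    z_range: tuple[int, int]
    y_range: tuple[int, int]
    x_range: tuple[int, int]
    role: str = "signal"

    def __post_init__(self) -> None:
        if self.role not in ("signal", "background"):
            raise ValueError("role must be 'signal' or 'background'")
        for lo, hi in (self.z_range, self.y_range, self.x_range):
            if hi <= lo or lo < 0:
                raise ValueError("ROI ranges must be non-empty and non-negative")

    def extract(self, stack: ImageStack) -> np.ndarray:
        shape = stack.geometry.shape
        for (lo, hi), n in zip((self.z_range, self.y_range, self.x_range), shape):
            if hi > n:
                raise ValueError("ROI exceeds stack bounds")
        return stack.data[
            self.z_range[0] : self.z_range[1],
            self.y_range[0] : self.y_range[1],
            self.x_range[0] : self.x_range[1],
        ]


def compute_snr(
    stack: ImageStack,
    signal_roi: RegionOfInterest,
    background_roi: RegionOfInterest,
) -> float:
    """Mean of the signal ROI over the sample standard deviation of the background ROI."""
    sig = signal_roi.extract(stack).astype(float)
    bg = background_roi.extract(stack).astype(float)
    if bg.size < 2:
        raise ValueError("background ROI must contain more than one voxel")
    sd = bg.std(ddof=1)
    if sd == 0:
        raise ValueError("background ROI has zero variance")
    return float(sig.mean() / sd)


def rate_snr_stability(
    snr_t, snr_ref, tolerance: float = 0.10, min_regions: int = 3
) -> bool:
    """Stable iff every paired SNR ratio is within ``tolerance`` of 1.

    Requires at least ``min_regions`` paired reference regions.
    """
    t = np.asarray(snr_t, dtype=float)
    r = np.asarray(snr_ref, dtype=float)
    if t.shape != r.shape:
        raise ValueError("paired SNR lists must have equal length")
    if len(t) < min_regions:
        raise ValueError(f"at least {min_regions} reference regions are required")
    if np.any(r == 0):
        raise ValueError("reference SNR values must be nonzero")
    # small epsilon keeps exact-boundary ratios (e.g. 7.7/7.0) stable in float
    return bool(np.all(np.abs(t / r - 1.0) <= tolerance + 1e-9))


def _kde_profile(
    z_um: np.ndarray, grid: np.ndarray, bandwidth
) -> np.ndarray:
    """Count-scaled Gaussian KDE along z: cells per µm on the grid."""
    z = np.asarray(z_um, dtype=float)
    n = len(z)
    if isinstance(bandwidth, str):
        if bandwidth != "silverman":
            raise ValueError(f"unknown bandwidth rule {bandwidth!r}")
        sd = z.std(ddof=1) if n > 1 else 0.0
        iqr = np.subtract(*np.percentile(z, [75, 25]))
        spread = min(sd, iqr / 1.34) if iqr > 0 else sd
        bw = 0.9 * spread * n ** (-1 / 5)
        if bw <= 0:
            bw = 1.0  # degenerate spread; fall back to a 1 µm kernel
    else:
        bw = float(bandwidth)
        if bw <= 0:
            raise ValueError("bandwidth must be positive")
    diff = (grid[:, None] - z[None, :]) / bw
    dens = np.exp(-0.5 * diff**2).sum(axis=1) / (bw * np.sqrt(2 * np.pi))
    return dens  # integrates to ~n over the real line


@dataclass(frozen=True)
class DensityScore:
    score_cells: float
    flagged: bool
    threshold: float = DENSITY_SCORE_THRESHOLD


def density_profile_score(
    table_t: pd.DataFrame,
    table_ref: pd.DataFrame,
    total_depth_um: float = 700.0,
    grid_points: int = 512,
    bandwidth="silverman",
    threshold: float = DENSITY_SCORE_THRESHOLD,
) -> DensityScore:
    """Integrated absolute difference of count-scaled z-density profiles.

    Each table's depth distribution is kernel-density estimated on a common
    grid over [0, depth] and scaled by its nucleus count to cells-per-µm; the
    score is the trapezoidal integral of the absolute difference, in cells.
    Scores above ``threshold`` flag the dataset for manual review.
    """
    for name, tbl in (("table_t", table_t), ("table_ref", table_ref)):
        if len(tbl) == 0:
            raise ValueError(f"{name} is empty")
        if "z_um" not in tbl.columns:
            raise ValueError(f"{name} lacks a z_um column")
    grid = np.linspace(0.0, total_depth_um, grid_points)
    prof_t = _kde_profile(table_t["z_um"].to_numpy(), grid, bandwidth)
    prof_r = _kde_profile(table_ref["z_um"].to_numpy(), grid, bandwidth)
    score = float(np.trapezoid(np.abs(prof_t - prof_r), grid))
    return DensityScore(score, score > threshold, threshold)


def detect_blankouts(stack: ImageStack, fraction: float = 0.05) -> np.ndarray:
    """Indices of z planes whose mean intensity collapses below ``fraction`` × median.

    An all-zero stack flags every plane.
    """
    means = stack.data.reshape(stack.data.shape[0], -1).mean(axis=1)
    med = np.median(means)
    return np.flatnonzero(means <= fraction * med)


@dataclass
class QCReport:
    """Exclusion decision for one (animal, position, timepoint-pair)."""

    animal_id: str
    position_id: str
    timepoint_pair: tuple
    snr_t: tuple = ()
    snr_ref: tuple = ()
    snr_stable: bool | None = None
    density_score: float | None = None
    density_flagged: bool = False
    blankout_planes: tuple = ()
    inhomogeneity_suspect: bool = False
    reasons: list = field(default_factory=list)

    @property
    def excluded(self) -> bool:
        return len(self.reasons) > 0

    def to_row(self) -> dict:
        return {
            "animal_id": self.animal_id,
            "position_id": self.position_id,
            "timepoint_pair": str(self.timepoint_pair),
            "snr_stable": self.snr_stable,
            "density_score": self.density_score,
            "density_flagged": self.density_flagged,
            "n_blankout_planes": len(self.blankout_planes),
            "inhomogeneity_suspect": self.inhomogeneity_suspect,
            "excluded": self.excluded,
            "reasons": ";".join(self.reasons),
        }


def build_qc_report(
    animal_id: str,
    position_id: str,
    timepoint_pair: tuple,
    stack_t: ImageStack | None = None,
    snr_t=None,
    snr_ref=None,
    table_t: pd.DataFrame | None = None,
    table_ref: pd.DataFrame | None = None,
    inhomogeneity_suspect: bool = False,
    snr_tolerance: float = 0.10,
    density_threshold: float = DENSITY_SCORE_THRESHOLD,
    blankout_fraction: float = 0.05,
) -> QCReport:
    """Assemble the exclusion decision from the individual criteria.

    Inhomogeneity screening is a manual call (identified by eye on matched
    frames), so it enters only as a caller-supplied flag.
    """
    report = QCReport(animal_id, position_id, tuple(timepoint_pair))
    if stack_t is not None:
        planes = detect_blankouts(stack_t, blankout_fraction)
        report.blankout_planes = tuple(int(p) for p in planes)
        if len(planes):
            report.reasons.append("blankout")
    if snr_t is not None and snr_ref is not None:
        report.snr_t = tuple(float(v) for v in np.atleast_1d(snr_t))
        report.snr_ref = tuple(float(v) for v in np.atleast_1d(snr_ref))
        report.snr_stable = rate_snr_stability(snr_t, snr_ref, tolerance=snr_tolerance)
        if not report.snr_stable:
            report.reasons.append("snr-unstable")
    if table_t is not None and table_ref is not None:
        score = density_profile_score(table_t, table_ref, threshold=density_threshold)
        report.density_score = score.score_cells
        report.density_flagged = score.flagged
        if score.flagged:
            report.reasons.append("density-flag")
    if inhomogeneity_suspect:
        report.inhomogeneity_suspect = True
        report.reasons.append("inhomogeneity-suspect")
    return report
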