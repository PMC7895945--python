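"""Per-stack cellular metrics.

Counts (whole stack and depth-binned), 3D nearest-neighbor distances, nucleus
volume statistics with size-category fractions, relative changes versus
baseline, and assembly of the long correlation table joining cellular metrics
with mask-level volume change.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

logger = logging.getLogger(__name__)

__all__ = [
    "DepthBinning",
    "SizeCategories",
    "DepthCounts",
    "NearestNeighborResult",
    "VolumeStats",
    "count_by_depth",
    "nearest_neighbor_stats",
    "nucleus_volume_stats",
    "relative_change",
    "build_correlation_table",
]

REQUIRED_COLUMNS = ("x_um", "y_um", "z_um", "volume_um3")


@dataclass(frozen=True)
class DepthBinning:
    """Half-open depth bins [a, b) over [0, depth]; the last bin is closed."""

    bin_width_um: float = 175.0
    total_depth_um: float = 700.0

    def __post_init__(self) -> None:
        if self.bin_width_um <= 0 or self.total_depth_um <= 0:
            raise ValueError("bin width and total depth must be positive")
        n = self.total_depth_um / self.bin_width_um
        if abs(n - round(n)) > 1e-9:
            raise ValueError("bin width must partition the total depth exactly")

    @property
    def n_bins(self) -> int:
        return int(round(self.total_depth_um / self.bin_width_um))

    @property
    def edges(self) -> np.ndarray:
        return np.linspace(0.0, self.total_depth_um, self.n_bins + 1)

    def assign(self, z_um: np.ndarray) -> np.ndarray:
        """Bin index per depth; -1 for out-of-range values."""
        z = np.asarray(z_um, dtype=float)
        idx = np.floor(z / self.bin_width_um).astype(int)
        idx[z == self.total_depth_um] = self.n_bins - 1  # last bin closed
        idx[(z < 0) | (z > self.total_depth_um)] = -1
        return idx


@dataclass(frozen=True)
class SizeCategories:
    """Left-closed size categories in µm³; the last bin is closed on the right.

    Volumes above the last edge count toward a separate overflow fraction.
    """

    edges_um3: tuple = (0.0, 750.0, 1500.0, 2250.0, 3000.0)

    def __post_init__(self) -> None:
        e = np.asarray(self.edges_um3, dtype=float)
        if len(e) < 2 or np.any(np.diff(e) <= 0):
            raise ValueError("edges must be strictly increasing")
        object.__setattr__(self, "edges_um3", tuple(e))

    @property
    def n_categories(self) -> int:
        return len(self.edges_um3) - 1

    def assign(self, volumes_um3: np.ndarray) -> np.ndarray:
        """Category index per volume; n_categories for overflow, -1 below range."""
        v = np.asarray(volumes_um3, dtype=float)
        e = np.asarray(self.edges_um3)
        idx = np.searchsorted(e, v, side="right") - 1
        idx[v == e[-1]] = self.n_categories - 1  # closed right edge on last bin
        idx[v > e[-1]] = self.n_categories
        idx[v < e[0]] = -1
        return idx


def _check_table(table: pd.DataFrame) -> None:
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"nucleus table is missing columns: {missing}")


@dataclass(frozen=True)
class DepthCounts:
    counts: np.ndarray  # per-bin counts
    total: int  # in-range total
    n_excluded: int  # out-of-range rows


def count_by_depth(table: pd.DataFrame, binning: DepthBinning | None = None) -> DepthCounts:
    """Count nuclei per depth bin; out-of-range depths are excluded and logged."""
    binning = binning or DepthBinning()
    _check_table(table)
    idx = binning.assign(table["z_um"].to_numpy())
    excluded = int(np.count_nonzero(idx < 0))
    if excluded:
        logger.warning("count_by_depth: %d nuclei outside [0, %g] µm excluded",
                       excluded, binning.total_depth_um)
    counts = np.bincount(idx[idx >= 0], minlength=binning.n_bins)
    return DepthCounts(counts, int(counts.sum()), excluded)


@dataclass(frozen=True)
class NearestNeighborResult:
    distances_um: np.ndarray  # aligned with the input rows
    mean_um: float
    bin_means_um: np.ndarray | None = None  # per depth bin; NaN where empty


def nearest_neighbor_stats(
    table: pd.DataFrame, binning: DepthBinning | None = None
) -> NearestNeighborResult:
    """3D Euclidean nearest-neighbor distance per nucleus plus the stack mean.

    When ``binning`` is given, per-bin means are also returned: each nucleus is
    assigned by its own depth while the neighbor search spans the whole stack.
    """
    _check_table(table)
    pts = table[["x_um", "y_um", "z_um"]].to_numpy(dtype=float)
    if len(pts) < 2:
        raise ValueError("nearest-neighbor statistics require at least 2 nuclei")
    dist, _ = cKDTree(pts).query(pts, k=2)
    nn = dist[:, 1]
    bin_means = None
    if binning is not None:
        idx = binning.assign(pts[:, 2])
        bin_means = np.full(binning.n_bins, np.nan)
        for b in range(binning.n_bins):
            sel = idx == b
            if sel.any():
                bin_means[b] = nn[sel].mean()
    return NearestNeighborResult(nn, float(nn.mean()), bin_means)


@dataclass(frozen=True)
class VolumeStats:
    mean_um3: float
    category_fractions: np.ndarray
    overflow_fraction: float
    n: int


def nucleus_volume_stats(
    table: pd.DataFrame, categories: SizeCategories | None = None
) -> VolumeStats:
    """Mean nucleus volume and size-category fractions (denominator: all nuclei)."""
    categories = categories or SizeCategories()
    _check_table(table)
    v = table["volume_um3"].to_numpy(dtype=float)
    if len(v) == 0:
        raise ValueError("nucleus table is empty")
    idx = categories.assign(v)
    n = len(v)
    fractions = np.array(
        [np.count_nonzero(idx == k) / n for k in range(categories.n_categories)]
    )
    overflow = np.count_nonzero(idx == categories.n_categories) / n
    return VolumeStats(float(v.mean()), fractions, float(overflow), n)


def relative_change(value_t: float, value_baseline: float) -> float:
    """Value at a timepoint as a percentage of its baseline."""
    if value_baseline == 0:
        raise ValueError("baseline value must be nonzero")
    return 100.0 * value_t / value_baseline


def build_correlation_table(
    metric_table: pd.DataFrame,
    gmv_table: pd.DataFrame,
    keys: tuple = ("animal_id", "position_id", "interval"),
) -> pd.DataFrame:
    """Inner-join per-position metric changes with mask-level volume change.

    Both inputs must be uniquely keyed by ``keys``; rows present on only one
    side are dropped (and logged).
    """
    keys = list(keys)
    for name, df in (("metric", metric_table), ("gmv", gmv_table)):
        missing = [k for k in keys if k not in df.columns]
        if missing:
            raise ValueError(f"{name} table is missing key columns {missing}")
        if df.duplicated(subset=keys).any():
            raise ValueError(f"duplicate keys in the {name} table")
    joined = metric_table.merge(gmv_table, on=keys, how="inner")
    dropped = len(metric_table) + len(gmv_table) - 2 * len(joined)
    if dropped:
        logger.warning("build_correlation_table: %d unmatched rows dropped", dropped)
    return joined
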