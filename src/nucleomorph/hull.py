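"""Convex-hull tissue volumetry from fiducial landmarks.

The tissue volume between re-identified landmark nuclei is measured as the
volume of their convex hull, computed twice — as the sum of Delaunay
tetrahedron volumes and directly from the hull facets — and cross-checked.
Layer-confined volumes assign whole tetrahedra to depth bins by centroid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull, Delaunay, QhullError

from .errors import DegenerateGeometryError
from .metrics import DepthBinning

__all__ = ["ConvexHullResult", "FiducialSet", "hull_volume", "layer_volumes", "hull_change_series"]

FIDUCIAL_COLUMNS = ("fiducial_id", "x_um", "y_um", "z_um")


@dataclass(frozen=True)
class ConvexHullResult:
    """Hull volume with its tetrahedral decomposition."""

    volume_um3: float  # Delaunay tetra-volume sum
    direct_volume_um3: float  # independent facet-based hull volume
    tetrahedra: np.ndarray  # (m, 4) vertex indices
    tetra_volumes_um3: np.ndarray  # (m,) unsigned volumes
    hull_vertices: np.ndarray  # indices of hull vertices
    points_um: np.ndarray  # (n, 3) input copy

    def cross_check(self, rtol: float = 1e-9) -> bool:
        return bool(
            np.isclose(self.volume_um3, self.direct_volume_um3, rtol=rtol, atol=0.0)
        )


def _diagnose_degenerate(pts: np.ndarray) -> str | None:
    uniq = np.unique(pts, axis=0)
    if len(uniq) < len(pts):
        return "duplicate points"
    rank = np.linalg.matrix_rank(
        pts - pts.mean(axis=0), tol=1e-9 * max(1.0, float(np.abs(pts).max()))
    )
    if rank <= 1:
        return "collinear points"
    if rank == 2:
        return "coplanar points"
    return None


def hull_volume(points_um: np.ndarray) -> ConvexHullResult:
    """Delaunay triangulation plus direct convex-hull volume of a 3D point set.

    Requires at least 4 affinely independent points; degenerate inputs raise a
    :class:`DegenerateGeometryError` naming the offending condition.
    """
    pts = np.asarray(points_um, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise ValueError("points must be an (n, 3) array")
    if len(pts) < 4:
        raise DegenerateGeometryError("at least 4 points are required")
    reason = _diagnose_degenerate(pts)
    if reason is not None:
        raise DegenerateGeometryError(f"degenerate input: {reason}")
    try:
        tri = Delaunay(pts)
        hull = ConvexHull(pts)
    except QhullError as exc:  # pragma: no cover - diagnosed above in practice
        raise DegenerateGeometryError(f"qhull failed on degenerate input: {exc}") from exc
    simplices = tri.simplices
    a = pts[simplices[:, 1]] - pts[simplices[:, 0]]
    b = pts[simplices[:, 2]] - pts[simplices[:, 0]]
    c = pts[simplices[:, 3]] - pts[simplices[:, 0]]
    vols = np.abs(np.einsum("ij,ij->i", a, np.cross(b, c))) / 6.0
    return ConvexHullResult(
        volume_um3=float(vols.sum()),
        direct_volume_um3=float(hull.volume),
        tetrahedra=simplices.copy(),
        tetra_volumes_um3=vols,
        hull_vertices=hull.vertices.copy(),
        points_um=pts.copy(),
    )


def layer_volumes(result: ConvexHullResult, binning: DepthBinning) -> np.ndarray:
    """Sum tetrahedron volumes per depth bin, assigning by tetra-centroid z.

    Whole tetrahedra are assigned (no clipping at bin boundaries), so layer
    volumes are approximate but always sum exactly to the total.
    """
    centroid_z = result.points_um[result.tetrahedra][:, :, 2].mean(axis=1)
    idx = binning.assign(centroid_z)
    if np.any(idx < 0):
        bad = np.flatnonzero(idx < 0)
        raise ValueError(
            f"tetrahedron centroids outside the binning range: indices {bad.tolist()}"
        )
    return np.bincount(idx, weights=result.tetra_volumes_um3, minlength=binning.n_bins)


class FiducialSet:
    """Matched landmark coordinates across declared timepoints.

    ``table`` must carry columns ``timepoint, fiducial_id, x_um, y_um, z_um``
    for one (animal, position).  Ids must be unique within each timepoint.
    """

    def __init__(self, table: pd.DataFrame, timepoints: list | None = None) -> None:
        missing = [c for c in ("timepoint",) + FIDUCIAL_COLUMNS if c not in table.columns]
        if missing:
            raise ValueError(f"fiducial table is missing columns {missing}")
        self.table = table.copy()
        self.timepoints = (
            list(timepoints)
            if timepoints is not None
            else sorted(self.table["timepoint"].unique().tolist())
        )
        for tp in self.timepoints:
            sub = self.table[self.table["timepoint"] == tp]
            if sub["fiducial_id"].duplicated().any():
                raise ValueError(f"duplicate fiducial ids at timepoint {tp!r}")

    def complete_ids(self) -> np.ndarray:
        """Ids present at every declared timepoint (sorted)."""
        sets = [
            set(self.table.loc[self.table["timepoint"] == tp, "fiducial_id"])
            for tp in self.timepoints
        ]
        common = set.intersection(*sets) if sets else set()
        return np.array(sorted(common))

    def coordinates(self, timepoint, ids: np.ndarray) -> np.ndarray:
        sub = self.table[self.table["timepoint"] == timepoint].set_index("fiducial_id")
        return sub.loc[list(ids), ["x_um", "y_um", "z_um"]].to_numpy(dtype=float)


def hull_change_series(
    fiducials: FiducialSet,
    baseline=None,
    binning: DepthBinning | None = None,
) -> pd.DataFrame:
    """Per-timepoint hull volume as a percentage of the baseline hull.

    Ids absent at any declared timepoint are dropped everywhere before any
    hull is built, so every hull uses the same landmark set.  Fewer than 4
    surviving ids is an error; fewer than 30 triggers a reliability warning.
    """
    ids = fiducials.complete_ids()
    if len(ids) < 4:
        raise DegenerateGeometryError(
            f"only {len(ids)} fiducials present at all timepoints; need at least 4"
        )
    if len(ids) < 30:
        warnings.warn(
            f"only {len(ids)} complete fiducials; more than 30 are recommended "
            "for reliable volume estimates"
        )
    baseline = fiducials.timepoints[0] if baseline is None else baseline
    if baseline not in fiducials.timepoints:
        raise ValueError(f"baseline timepoint {baseline!r} not declared")

    rows = []
    results = {}
    for tp in fiducials.timepoints:
        results[tp] = hull_volume(fiducials.coordinates(tp, ids))
    v0 = results[baseline].volume_um3
    layer0 = layer_volumes(results[baseline], binning) if binning is not None else None
    for tp in fiducials.timepoints:
        res = results[tp]
        row = {
            "timepoint": tp,
            "n_fiducials": len(ids),
            "volume_um3": res.volume_um3,
            "pct_of_baseline": 100.0 * res.volume_um3 / v0,
        }
        if binning is not None:
            lv = layer_volumes(res, binning)
            for k in range(binning.n_bins):
                row[f"layer{k}_volume_um3"] = lv[k]
                row[f"layer{k}_pct_of_baseline"] = (
                    100.0 * lv[k] / layer0[k] if layer0[k] > 0 else np.nan
                )
        rows.append(row)
    return pd.DataFrame(rows)
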