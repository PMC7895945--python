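import numpy as np
import pandas as pd
import pytest

from nucleomorph.geometry import VoxelGeometry
from nucleomorph.synthetic import (
    GroundTruthField,
    ImagingModel,
    SizeMixture,
    render_stack,
    volume_to_radius_um,
)


@pytest.fixture
def desk_geometry():
    """Small desk-scale grid: 1x1x2 µm voxels, 200x200x200 µm."""
    return VoxelGeometry((100, 200, 200), (2.0, 1.0, 1.0))


def make_nucleus_table(points_xyz, volumes_um3=None, **keys):
    pts = np.asarray(points_xyz, dtype=float)
    v = np.ones(len(pts)) if volumes_um3 is None else np.asarray(volumes_um3, float)
    df = pd.DataFrame(
        {
            "animal_id": keys.get("animal_id", "A0"),
            "position_id": keys.get("position_id", "P0"),
            "timepoint": keys.get("timepoint", 0),
            "nucleus_id": np.arange(1, len(pts) + 1),
            "x_um": pts[:, 0],
            "y_um": pts[:, 1],
            "z_um": pts[:, 2],
            "volume_voxels": np.maximum(1, (v / 2.0)).astype(int),
            "volume_um3": v,
        }
    )
    return df


def make_grid_field(seed, n=200, extent=200.0, jitter=3.0, peak=8000.0):
    """Jittered-grid ground-truth field: n well-separated nuclei, 20 µm margins."""
    rng = np.random.default_rng(seed)
    grid = np.array(
        [
            [x, y, z]
            for z in np.arange(25, extent, 28.0)
            for y in np.arange(25, extent, 30.0)
            for x in np.arange(25, extent, 30.0)
        ]
    )
    assert len(grid) >= n
    sel = rng.choice(len(grid), n, replace=False)
    pos = grid[sel] + rng.uniform(-jitter, jitter, (n, 3))
    classes, vols = SizeMixture().sample(n, rng)
    r = volume_to_radius_um(vols)
    field = GroundTruthField(
        ids=np.arange(1, n + 1),
        centroids_um=pos,
        radii_um=np.stack([r, r, r], axis=1),
        peaks=np.full(n, peak),
        classes=classes,
        extent_um=(extent, extent, extent),
    )
    field.validate()
    return field


def render_recovery_phantom(seed, geometry, noise_frac=0.05, peak=8000.0):
    """Rendered 200-nucleus phantom with noise sd = noise_frac × peak."""
    field = make_grid_field(seed, peak=peak)
    imaging = ImagingModel(
        attenuation_length_um=1e9,
        background_offset=100.0,
        noise_sd=noise_frac * peak,
    )
    stack = render_stack(field, geometry, imaging, seed=seed + 1)
    return field, stack
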