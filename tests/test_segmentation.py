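import numpy as np
import pandas as pd
import pytest
from scipy import ndimage
from scipy.spatial import cKDTree

from nucleomorph.geometry import VoxelGeometry
from nucleomorph.images import ImageStack, LabelVolume, ProbabilityMap
from nucleomorph.segmentation import (
    SegmentationConfig,
    compute_foreground_probability,
    detect_seeds,
    extract_nuclei,
    filter_and_resegment,
    probability_from_array,
    segment_stack,
    watershed_segment,
)

from conftest import render_recovery_phantom


def gaussian_blob_prob(geometry, centers_um, sigma_um, amplitude=0.9):
    """Sum of isotropic Gaussian blobs as a probability map."""
    zc, yc, xc = geometry.center_grids_um()
    data = np.zeros(geometry.shape, dtype=float)
    amps = np.broadcast_to(np.asarray(amplitude, float), (len(centers_um),))
    for (x, y, z), a in zip(centers_um, amps):
        data += a * np.exp(
            -((zc - z) ** 2 + (yc - y) ** 2 + (xc - x) ** 2) / (2 * sigma_um**2)
        )
    return ProbabilityMap(np.clip(data, 0, 1), geometry)


@pytest.fixture
def geom():
    return VoxelGeometry((20, 40, 100), (2.0, 1.0, 1.0))


class TestComputeForegroundProbability:
    def test_constant_stack_maps_to_zero(self, geom):
        stack = ImageStack(np.full(geom.shape, 500, dtype=np.uint16), geom)
        prob = compute_foreground_probability(stack)
        assert np.all(prob.data == 0.0)

    def test_bright_blob_max_near_center(self, geom):
        zc, yc, xc = geom.center_grids_um()
        img = 100 + 4000 * np.exp(
            -((zc - 20.0) ** 2 + (yc - 20.0) ** 2 + (xc - 50.0) ** 2) / (2 * 6.0**2)
        )
        stack = ImageStack(img.astype(np.uint16), geom)
        prob = compute_foreground_probability(stack, smoothing_sd_um=1.0)
        # the 99.9th-percentile rescale saturates a plateau; use its centroid
        peak = ndimage.center_of_mass(prob.data == prob.data.max())
        center_idx = geom.um_to_index(np.array([20.0, 20.0, 50.0]))
        assert np.all(np.abs(np.array(peak) - center_idx) <= 1.0)

    def test_external_map_passthrough(self, geom):
        rng = np.random.default_rng(0)
        data = rng.random(geom.shape)
        prob = probability_from_array(data, geom)
        assert np.array_equal(prob.data, data)

    def test_out_of_range_external_map_rejected(self, geom):
        with pytest.raises(ValueError):
            probability_from_array(np.full(geom.shape, 1.5), geom)


class TestDetectSeeds:
    def test_single_blob_single_seed_near_peak(self, geom):
        prob = gaussian_blob_prob(geom, [(50.0, 20.0, 20.0)], 8.0)
        cfg = SegmentationConfig(foreground_threshold=0.2, seed_prominence=0.1)
        seeds = detect_seeds(prob, cfg)
        assert len(seeds.labels) == 1
        com = ndimage.center_of_mass(seeds.data > 0)
        assert np.all(np.abs(np.array(com) - geom.um_to_index([20.0, 20.0, 50.0])) <= 2.0)

    def test_all_zero_map_gives_no_seeds(self, geom):
        prob = ProbabilityMap(np.zeros(geom.shape), geom)
        cfg = SegmentationConfig()
        assert len(detect_seeds(prob, cfg).labels) == 0

    def test_two_blobs_20um_apart_give_two_seeds(self, geom):
        prob = gaussian_blob_prob(geom, [(40.0, 20.0, 20.0), (60.0, 20.0, 20.0)], 4.0)
        cfg = SegmentationConfig(foreground_threshold=0.2, seed_prominence=0.1)
        assert len(detect_seeds(prob, cfg).labels) == 2


class TestWatershedSegment:
    def test_single_seed_claims_suprathreshold_component(self, geom):
        prob = gaussian_blob_prob(geom, [(50.0, 20.0, 20.0)], 8.0)
        cfg = SegmentationConfig(foreground_threshold=0.3, seed_prominence=0.1)
        seeds = detect_seeds(prob, cfg)
        out = watershed_segment(prob, seeds, cfg)
        expected, _ = ndimage.label(prob.data >= 0.3)
        assert np.array_equal(out.data > 0, expected > 0)
        assert len(out.labels) == 1

    def test_empty_seeds_warn_and_return_background(self, geom):
        prob = gaussian_blob_prob(geom, [(50.0, 20.0, 20.0)], 8.0)
        cfg = SegmentationConfig()
        empty = LabelVolume(np.zeros(geom.shape, dtype=np.int32), geom, "seeds")
        with pytest.warns(UserWarning, match="no seeds"):
            out = watershed_segment(prob, empty, cfg)
        assert out.data.max() == 0

    def test_fused_double_blob_splits_at_analytic_saddle(self, geom):
        # equal blobs at x = 35 and 65: the probability saddle is the plane x = 50
        prob = gaussian_blob_prob(geom, [(35.0, 20.0, 20.0), (65.0, 20.0, 20.0)], 8.0)
        cfg = SegmentationConfig(foreground_threshold=0.2, seed_prominence=0.1)
        seeds = detect_seeds(prob, cfg)
        assert len(seeds.labels) == 2
        out = watershed_segment(prob, seeds, cfg)
        assert len(out.labels) == 2
        sizes = np.bincount(out.data.ravel())[1:]
        assert sizes[0] == sizes[1]  # symmetric split
        # every boundary between the two labels lies within 1 voxel of x = 50
        lab = out.data
        adjacent = (lab[:, :, :-1] > 0) & (lab[:, :, 1:] > 0) & (lab[:, :, :-1] != lab[:, :, 1:])
        xs = np.where(adjacent.any(axis=(0, 1)))[0]
        assert np.all(np.abs((xs + 1.0) - 50.0) <= 1.0)


class TestFilterAndResegment:
    def _labels_with_block(self, geom, shape_vox, value=1):
        lab = np.zeros(geom.shape, dtype=np.int32)
        lab[: shape_vox[0], : shape_vox[1], : shape_vox[2]] = value
        return LabelVolume(lab, geom, "raw")

    def test_small_object_removed(self, geom):
        labels = self._labels_with_block(geom, (10, 10, 10))  # 1000 voxels
        prob = ProbabilityMap(np.ones(geom.shape) * 0.6, geom)
        out = filter_and_resegment(labels, prob, SegmentationConfig())
        assert out.data.max() == 0

    def test_within_bounds_objects_kept(self):
        geom = VoxelGeometry((30, 50, 50), (2.0, 1.0, 1.0))
        lab = np.zeros(geom.shape, dtype=np.int32)
        lab[:20, :10, :10] = 1  # 2000 voxels
        lab[:10, 20:45, 10:50] = 2  # 10000 voxels
        prob = ProbabilityMap(np.ones(geom.shape) * 0.6, geom)
        out = filter_and_resegment(LabelVolume(lab, geom, "raw"), prob, SegmentationConfig())
        sizes = np.sort(np.bincount(out.data.ravel())[1:])
        assert np.array_equal(sizes, [2000, 10000])

    def test_fused_twin_blob_split_into_two(self):
        # ~23k-voxel fused pair: shallow mutual saddle hides the second seed at
        # h = 0.3 but reveals it at the lowered re-segmentation threshold
        geom = VoxelGeometry((40, 80, 140), (2.0, 1.0, 1.0))
        prob = gaussian_blob_prob(
            geom, [(50.0, 40.0, 40.0), (90.0, 40.0, 40.0)], 12.0, amplitude=0.55
        )
        cfg = SegmentationConfig(
            foreground_threshold=0.2,
            seed_prominence=0.3,
            min_voxels=1500,
            max_voxels=18000,
            reseg_threshold_factor=0.5,
        )
        seeds = detect_seeds(prob, cfg)
        assert len(seeds.labels) == 1  # merged: saddle depth < prominence
        raw = watershed_segment(prob, seeds, cfg)
        assert len(raw.labels) == 1
        assert np.count_nonzero(raw.data) > 18000
        out = filter_and_resegment(raw, prob, cfg)
        sizes = np.bincount(out.data.ravel())[1:]
        assert len(sizes) == 2
        assert np.all(sizes >= 1500)

    def test_idempotent_on_conforming_labels(self):
        geom = VoxelGeometry((30, 50, 50), (2.0, 1.0, 1.0))
        lab = np.zeros(geom.shape, dtype=np.int32)
        lab[:20, :10, :10] = 3
        lab[:10, 20:45, 10:50] = 7
        prob = ProbabilityMap(np.ones(geom.shape) * 0.6, geom)
        cfg = SegmentationConfig()
        once = filter_and_resegment(LabelVolume(lab, geom, "raw"), prob, cfg)
        twice = filter_and_resegment(once, prob, cfg)
        # identity up to (consecutive) relabeling
        assert np.array_equal(once.data > 0, twice.data > 0)
        for v in np.unique(once.data[once.data > 0]):
            vals = np.unique(twice.data[once.data == v])
            assert len(vals) == 1

    def test_failed_resegmentation_retains_and_flags(self):
        geom = VoxelGeometry((30, 60, 60), (2.0, 1.0, 1.0))
        lab = np.zeros(geom.shape, dtype=np.int32)
        lab[:30, :50, :50] = 1  # 75000 voxels, above max
        # flat probability: no local maxima anywhere, re-seeding finds nothing
        prob = ProbabilityMap(np.full(geom.shape, 0.6), geom)
        cfg = SegmentationConfig()
        out = filter_and_resegment(LabelVolume(lab, geom, "raw"), prob, cfg)
        assert len(out.labels) == 1
        assert out.flagged_labels == (1,)


class TestExtractNuclei:
    def test_volume_um3_from_voxel_count(self):
        geom = VoxelGeometry((10, 10, 10), (2.0, 1.0, 1.0))
        lab = np.zeros(geom.shape, dtype=np.int32)
        lab[0, 0, :10] = 1  # 10 voxels
        table = extract_nuclei(LabelVolume(lab, geom, "filtered"))
        assert table.loc[0, "volume_voxels"] == 10
        assert table.loc[0, "volume_um3"] == pytest.approx(20.0)

    def test_symmetric_object_centroid_at_center(self):
        geom = VoxelGeometry((11, 11, 11), (2.0, 1.0, 1.0))
        lab = np.zeros(geom.shape, dtype=np.int32)
        lab[3:8, 2:9, 4:7] = 2
        table = extract_nuclei(LabelVolume(lab, geom, "filtered"))
        assert table.loc[0, "z_um"] == pytest.approx((3 + 7) / 2 * 2 + 1.0)
        assert table.loc[0, "y_um"] == pytest.approx((2 + 8) / 2 + 0.5)
        assert table.loc[0, "x_um"] == pytest.approx((4 + 6) / 2 + 0.5)

    def test_matches_bruteforce_single_pass_oracle(self):
        rng = np.random.default_rng(3)
        geom = VoxelGeometry((12, 15, 18), (2.0, 1.0, 0.5))
        lab = rng.integers(0, 5, size=geom.shape).astype(np.int32)
        table = extract_nuclei(LabelVolume(lab, geom, "filtered")).set_index("nucleus_id")
        # independent brute-force accumulation, voxel by voxel
        sums = {}
        for iz in range(12):
            for iy in range(15):
                for ix in range(18):
                    v = lab[iz, iy, ix]
                    if v == 0:
                        continue
                    acc = sums.setdefault(v, [0, 0.0, 0.0, 0.0])
                    acc[0] += 1
                    acc[1] += (ix + 0.5) * 0.5
                    acc[2] += (iy + 0.5) * 1.0
                    acc[3] += (iz + 0.5) * 2.0
        for v, (n, sx, sy, sz) in sums.items():
            row = table.loc[v]
            assert row["volume_voxels"] == n
            assert row["x_um"] == pytest.approx(sx / n)
            assert row["y_um"] == pytest.approx(sy / n)
            assert row["z_um"] == pytest.approx(sz / n)
            assert row["volume_um3"] == pytest.approx(n * 1.0)

    def test_empty_labels_give_empty_table(self):
        geom = VoxelGeometry((5, 5, 5), (2.0, 1.0, 1.0))
        table = extract_nuclei(LabelVolume(np.zeros(geom.shape, np.int32), geom, "filtered"))
        assert len(table) == 0


class TestEndToEnd:
    RECOVERY_CFG = SegmentationConfig(
        foreground_threshold=0.18,  # calibrated on ground-truth phantoms
        seed_prominence=0.1,
        min_voxels=50,
        max_voxels=500_000,
    )

    def test_pipeline_deterministic(self, desk_geometry):
        field, stack = render_recovery_phantom(21, desk_geometry)
        _, t1 = segment_stack(stack, self.RECOVERY_CFG)
        _, t2 = segment_stack(stack, self.RECOVERY_CFG)
        pd.testing.assert_frame_equal(t1, t2)

    def test_recovery_on_rendered_phantom(self, desk_geometry):
        field, stack = render_recovery_phantom(22, desk_geometry)
        _, table = segment_stack(stack, self.RECOVERY_CFG)
        assert len(table) == field.n
        det = table[["x_um", "y_um", "z_um"]].to_numpy()
        d, idx = cKDTree(det).query(field.centroids_um)
        lateral = np.abs(det[idx][:, :2] - field.centroids_um[:, :2])
        assert lateral.max() < 1.0  # < 1 voxel at 1 µm in-plane
        mape = np.mean(
            np.abs(table["volume_um3"].to_numpy()[idx] - field.volumes_um3)
            / field.volumes_um3
        )
        assert mape < 0.15

    def test_min_voxels_invariant_holds(self, desk_geometry):
        field, stack = render_recovery_phantom(23, desk_geometry)
        labels, _ = segment_stack(stack, self.RECOVERY_CFG)
        sizes = np.bincount(labels.data.ravel())[1:]
        assert np.all(sizes[sizes > 0] >= self.RECOVERY_CFG.min_voxels)
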