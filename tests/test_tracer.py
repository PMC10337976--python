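"""Injection localization, peak extraction, segmentation, and tracer maps."""

import numpy as np
import pytest
from scipy import ndimage as ndi

from cortexstack import metrics, tracer
from cortexstack.tracer import (classify_laminar, combine_max, extract_peaks,
                                locate_injection_site, normalized_intensity,
                                rasterize_points, segment_tracer_by_intensity,
                                tracer_density)
from cortexstack.volgeom import Mask, PointSet, VoxelGrid


def _grid(data, spacing=50.0):
    return VoxelGrid(np.asarray(data, dtype=float), np.full(3, spacing),
                     np.zeros(3))


class TestLocateInjection:
    def test_phantom_blob_overlaps_truth_core(self, stpt):
        vol, truth = stpt
        ch3 = VoxelGrid(vol.data[..., 2], vol.spacing, vol.origin)
        site = locate_injection_site(ch3)
        assert metrics.dice(site.mask, truth.injection) >= 0.7
        # centroid lands inside the true injection sphere
        c_vox = np.round(truth.injection.world_to_voxel(site.centroid)).astype(int)
        assert truth.injection.data[tuple(c_vox)] == 1

    def test_dimmer_second_blob_is_rejected_by_half_max(self):
        data = np.zeros((40, 20, 20))
        data[8, 10, 10] = 100.0   # bright blob
        data[30, 10, 10] = 40.0   # 40% of max < half-max threshold
        site = locate_injection_site(_grid(data), sigma=100.0)
        idx = np.argwhere(site.mask.data)
        assert np.all(idx[:, 0] < 20)

    def test_invariant_to_uniform_intensity_rescaling(self, stpt):
        vol, _ = stpt
        ch3 = VoxelGrid(vol.data[..., 2], vol.spacing, vol.origin)
        a = locate_injection_site(ch3)
        b = locate_injection_site(ch3.like(ch3.data * 37.5))
        assert np.array_equal(a.mask.data, b.mask.data)

    def test_uniform_volume_is_degenerate_single_component(self, caplog):
        with caplog.at_level("WARNING"):
            site = locate_injection_site(_grid(np.ones((10, 10, 10))))
        assert site.mask.count == 1000
        assert any("degenerate" in r.message for r in caplog.records)

    def test_all_zero_volume_is_an_error(self):
        with pytest.raises(ValueError, match="no injection signal"):
            locate_injection_site(_grid(np.zeros((5, 5, 5))))

    def test_volume_accounts_voxel_size(self):
        data = np.zeros((20, 20, 20))
        data[10, 10, 10] = 1.0
        site = locate_injection_site(_grid(data, spacing=50.0), sigma=50.0)
        assert np.isclose(site.volume_mm3,
                          site.mask.count * (0.05 ** 3))


class TestExtractPeaks:
    def test_single_bump_yields_its_center(self):
        data = np.zeros((21, 21, 21))
        data[10, 10, 10] = 1.0
        prob = 0.9 * ndi.gaussian_filter(data, 2.0)
        prob /= prob.max() / 0.9
        cells = extract_peaks(_grid(prob))
        assert len(cells) == 1
        assert np.allclose(cells.points[0], [500, 500, 500])
        assert np.isclose(cells.probabilities[0], 0.9)

    def test_subthreshold_map_yields_empty_set(self, rng):
        prob = rng.uniform(0, 0.49, size=(10, 10, 10))
        assert len(extract_peaks(_grid(prob))) == 0

    def test_phantom_spots_recovered_with_high_recall_precision(self, stpt):
        vol, truth = stpt
        ch3 = vol.data[..., 2]
        prob = _grid(ch3 / ch3.max())
        prob.spacing = vol.spacing
        prob.origin = vol.origin
        cells = extract_peaks(prob, p_min=0.5, min_separation=100.0)
        d = np.linalg.norm(
            truth.cells.points[:, None, :] - cells.points[None, :, :], axis=-1)
        recall = np.mean(d.min(axis=1) <= 75.0)
        precision = np.mean(d.min(axis=0) <= 75.0)
        assert recall >= 0.95 and precision >= 0.95

    def test_invariant_under_monotone_transform(self, stpt):
        vol, _ = stpt
        ch3 = vol.data[..., 2]
        p1 = ch3 / ch3.max()
        p2 = p1 ** 3  # monotone, but moves the 0.5 crossing
        a = extract_peaks(_grid(p1), p_min=0.5)
        b = extract_peaks(_grid(p2), p_min=0.5 ** 3)
        assert np.allclose(np.sort(a.points, axis=0),
                           np.sort(b.points, axis=0))

    def test_plateau_collapses_to_centroid(self):
        data = np.zeros((11, 11, 3))
        data[4:7, 4:7, 1] = 0.8
        cells = extract_peaks(data)
        assert len(cells) == 1
        assert np.allclose(cells.points[0], [5, 5, 1])


class TestSegmentTracer:
    def test_equal_channels_give_empty_mask(self, rng):
        ch = rng.uniform(size=(20, 20, 20))
        assert segment_tracer_by_intensity(ch, ch).count == 0

    def test_phantom_fibers_recovered(self, stpt):
        vol, truth = stpt
        seg = segment_tracer_by_intensity(vol.data[..., 0], vol.data[..., 1],
                                          k_sd=3.0, injection=truth.injection)
        fibers = truth.tracer.data.astype(bool)
        recall = (seg.data.astype(bool) & fibers).sum() / fibers.sum()
        assert recall >= 0.9

    def test_threshold_nesting(self, stpt):
        vol, truth = stpt
        m3 = segment_tracer_by_intensity(vol.data[..., 0], vol.data[..., 1],
                                         k_sd=3.0, injection=truth.injection)
        m4 = segment_tracer_by_intensity(vol.data[..., 0], vol.data[..., 1],
                                         k_sd=4.0, injection=truth.injection)
        assert not np.any(m4.data & ~m3.data)

    def test_shape_mismatch_is_an_error(self):
        with pytest.raises(ValueError, match="shape"):
            segment_tracer_by_intensity(np.zeros((3, 3, 3)),
                                        np.zeros((3, 3, 4)))


class TestTracerDensity:
    def test_total_count_conserved_at_stpt_pixel_pitch(self, rng):
        masks = [rng.random((400, 380)) < 0.1 for _ in range(3)]
        vol = tracer_density(masks, pixel_pitch=(1.385, 1.339))
        assert vol.data.sum() == sum(int(m.sum()) for m in masks)
        assert np.allclose(vol.spacing, (50, 50, 50))

    def test_fully_positive_section_bins_all_pixel_centers(self):
        mask = np.ones((100, 100), dtype=bool)
        vol = tracer_density([mask], pixel_pitch=(1.385, 1.339))
        assert vol.data.sum() == 100 * 100
        # interior bins hold floor-binned pixel-center counts
        nx0 = int(np.sum(np.floor(np.arange(100) * 1.385 / 50) == 0))
        ny0 = int(np.sum(np.floor(np.arange(100) * 1.339 / 50) == 0))
        assert vol.data[0, 0, 0] == nx0 * ny0

    def test_empty_sections_give_zero_volume(self):
        vol = tracer_density([np.zeros((50, 50), bool)] * 2, (1.4, 1.4))
        assert vol.data.sum() == 0

    def test_single_pixel_lands_in_one_voxel(self):
        m = np.zeros((100, 100), bool)
        m[70, 30] = True
        vol = tracer_density([m], pixel_pitch=(1.385, 1.339))
        assert vol.data.sum() == 1
        assert vol.data[int(70 * 1.385 // 50), int(30 * 1.339 // 50), 0] == 1


class TestNormalizedIntensity:
    def _setup(self, stpt):
        vol, truth = stpt
        ch1 = VoxelGrid(vol.data[..., 0], vol.spacing, vol.origin)
        ch2 = VoxelGrid(vol.data[..., 1], vol.spacing, vol.origin)
        return ch1, ch2, truth

    def test_brightest_extra_injection_voxel_is_one(self, stpt):
        ch1, ch2, truth = self._setup(stpt)
        out, norm = normalized_intensity(ch1, ch2, truth.injection)
        excl = ndi.binary_dilation(truth.injection.data.astype(bool),
                                   iterations=2)
        assert np.isclose(out.data[~excl].max(), 1.0)
        assert norm > 0

    def test_scale_invariance(self, stpt):
        ch1, ch2, truth = self._setup(stpt)
        a, _ = normalized_intensity(ch1, ch2, truth.injection)
        b, _ = normalized_intensity(ch1.like(2 * ch1.data),
                                    ch2.like(2 * ch2.data), truth.injection)
        assert np.allclose(a.data, b.data)

    def test_saturated_injection_exceeds_one(self, stpt):
        ch1, ch2, truth = self._setup(stpt)
        out, _ = normalized_intensity(ch1, ch2, truth.injection)
        assert out.data[truth.injection.data.astype(bool)].max() > 1.0

    def test_no_signal_outside_injection_is_an_error(self):
        z = _grid(np.zeros((6, 6, 6)))
        inj = Mask(np.zeros((6, 6, 6)), z.spacing, z.origin)
        with pytest.raises(ValueError, match="no tracer signal"):
            normalized_intensity(z, z, inj)


class TestCombineMax:
    def test_single_map_is_identity(self, rng):
        v = _grid(rng.random((5, 5, 5)))
        assert np.allclose(combine_max([v]).data, v.data)

    def test_disjoint_supports_union(self):
        a = np.zeros((4, 4, 4)); a[0] = 1.0
        b = np.zeros((4, 4, 4)); b[2] = 2.0
        out = combine_max([_grid(a), _grid(b)])
        assert np.allclose(out.data, np.maximum(a, b))

    def test_associative_commutative_on_random_maps(self, rng):
        maps = [_grid(rng.random((6, 6, 6))) for _ in range(3)]
        ref = combine_max(maps).data
        for perm in ([2, 1, 0], [1, 2, 0]):
            assert np.allclose(combine_max([maps[i] for i in perm]).data, ref)
        nested = combine_max([combine_max(maps[:2]), maps[2]]).data
        assert np.allclose(nested, ref)

    def test_grid_mismatch_is_an_error(self, rng):
        a = _grid(rng.random((4, 4, 4)))
        b = VoxelGrid(rng.random((4, 4, 4)), (25, 25, 25), (0, 0, 0))
        with pytest.raises(ValueError, match="grid"):
            combine_max([a, b])


class TestRasterizePoints:
    def test_total_count_conserved(self, rng):
        pts = PointSet(rng.uniform(0, 1000, size=(200, 3)))
        vol = rasterize_points(pts, spacing=100.0,
                               extent=(np.zeros(3), np.full(3, 1000.0)))
        assert vol.data.sum() == 200

    def test_coarse_grid_equals_block_summed_fine_grid(self, rng):
        pts = PointSet(rng.uniform(0, 1600, size=(500, 3)))
        ext = (np.zeros(3), np.full(3, 1600.0))
        fine = rasterize_points(pts, 100.0, extent=ext).data
        coarse = rasterize_points(pts, 400.0, extent=ext).data
        blocked = fine.reshape(4, 4, 4, 4, 4, 4).sum(axis=(1, 3, 5))
        assert np.array_equal(coarse, blocked)

    def test_empty_set_gives_zero_volume(self):
        vol = rasterize_points(PointSet(np.empty((0, 3))), 100.0)
        assert vol.data.sum() == 0


class TestClassifyLaminar:
    def test_analytic_depth_on_shell(self, small_shell):
        # a point at analytic depth 0.9 is supragranular
        p_deep = 500 + 0.9 * 500  # radius for depth 0.9
        p_shallow = 500 + 0.2 * 500
        cells = PointSet([[p_deep, 0, 0], [p_shallow, 0, 0]])
        out = classify_laminar(cells, small_shell.depth_fn)
        assert list(out.labels) == ["supragranular", "infragranular"]

    def test_boundary_extremes(self, rng):
        cells = PointSet(rng.uniform(0, 1, size=(10, 3)))
        depth_of = lambda pts: np.full(len(pts), 0.5)
        assert all(classify_laminar(cells, depth_of, boundary=0.0).labels
                   == np.array(["supragranular"] * 10, dtype=object))
        assert all(classify_laminar(cells, depth_of, boundary=1.0).labels
                   == np.array(["infragranular"] * 10, dtype=object))

    def test_outside_cortex_is_unassigned(self):
        cells = PointSet([[0, 0, 0]])
        out = classify_laminar(cells, lambda p: np.array([np.nan]))
        assert out.labels[0] == "unassigned"
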