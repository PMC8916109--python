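"""Edge synthesis, compact watershed, region merging, probability
filtering, polygon refinement and seam handling."""

import numpy as np
import pytest
from scipy import ndimage
from shapely.geometry import Polygon, box

from fieldmapper import boundaries as bd
from fieldmapper.grids import GridSpec


class TestEdgeImage:
    def test_constant_inputs_zero_edges(self):
        comp = np.full((4, 20, 20), 0.3)
        prob = np.full((20, 20), 0.8)
        edges = bd.compute_edge_image(comp, prob)
        assert edges == pytest.approx(np.zeros((20, 20)), abs=1e-12)

    def test_vertical_step_peaks_at_step(self):
        comp = np.full((4, 20, 20), 0.2)
        comp[3, :, 10:] = 0.6  # NIR step only
        prob = np.full((20, 20), 0.5)
        params = bd.SegmentationParams(mean_shift_iters=0)
        edges = bd.compute_edge_image(comp, prob, params)
        col_mean = edges.mean(axis=0)
        assert col_mean.argmax() in (9, 10)
        assert edges[:, :5] == pytest.approx(0.0, abs=1e-9)

    def test_matches_direct_convolution_oracle(self):
        rng = np.random.default_rng(0)
        comp = rng.random((4, 64, 64))
        prob = rng.random((64, 64))
        params = bd.SegmentationParams(mean_shift_iters=0)
        edges = bd.compute_edge_image(comp, prob, params)

        smooth = np.array([1.0, 2.0, 1.0]) / 4.0
        deriv = np.array([1.0, 0.0, -1.0]) / 2.0
        kx = np.outer(smooth, deriv)
        ky = np.outer(deriv, smooth)

        def sobel_mag(img):
            # smoothed central differences; the sqrt(2) matches the
            # root-mean-square (per-axis) normalization of the gradient
            # magnitude used by the implementation
            gx = ndimage.convolve(img, kx, mode="reflect")
            gy = ndimage.convolve(img, ky, mode="reflect")
            return np.hypot(gx, gy) * np.sqrt(2)

        expected = np.zeros((64, 64))
        for i in (1, 2, 3):
            band = comp[i]
            band = (band - band.min()) / (band.max() - band.min())
            expected += sobel_mag(band)
        expected += sobel_mag(prob)
        assert edges == pytest.approx(expected, abs=1e-6)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            bd.compute_edge_image(np.zeros((4, 8, 8)), np.zeros((9, 9)))


class TestWatershed:
    def test_production_tile_segment_count_and_size(self):
        rng = np.random.default_rng(1)
        edges = rng.random((2000, 2000))
        labels = bd.initial_watershed(edges, 6400)
        ids, counts = np.unique(labels, return_counts=True)
        assert len(ids) == 6400
        assert counts.sum() == 2000 * 2000
        # mean segment area at native pixels (0.000025 deg ~ 2.78 m)
        px_ha = bd.area_ha(box(0, 0, 0.000025, 0.000025))
        assert counts.mean() * px_ha < 0.5

    def test_labels_partition_small_raster(self):
        edges = np.random.default_rng(2).random((40, 40))
        labels = bd.initial_watershed(edges, 16)
        assert len(np.unique(labels)) == 16
        assert labels.size == 1600

    def test_too_many_segments_rejected(self):
        with pytest.raises(ValueError):
            bd.initial_watershed(np.zeros((4, 4)), 17)


class TestMergeRegions:
    def _three_region_setup(self, a_val):
        # region C carries anchor values 0 and 1 so min-max normalization
        # leaves A and B's values untouched
        labels = np.array(
            [
                [1, 1, 2, 2],
                [1, 1, 2, 2],
                [3, 3, 3, 3],
                [3, 3, 3, 3],
            ]
        )
        band1 = np.zeros((4, 4))
        band1[labels == 1] = a_val
        band1[labels == 2] = 0.54
        band1[2] = [0.0, 1.0, 1.0, 1.0]
        band1[3] = [1.0, 1.0, 1.0, 1.0]
        band2 = np.zeros((4, 4))
        band2[labels == 1] = 0.2
        band2[labels == 2] = 0.2
        band2[labels == 3] = 0.9
        return labels, np.stack([band1, band2])

    def test_distance_just_below_threshold_merges(self):
        labels, bands = self._three_region_setup(a_val=0.50)  # distance 0.04
        merged = bd.merge_regions(labels, bands, threshold=0.05)
        assert len(np.unique(merged)) == 2
        assert merged[0, 0] == merged[0, 3]

    def test_distance_above_threshold_not_merged(self):
        labels, bands = self._three_region_setup(a_val=0.48)  # distance 0.06
        merged = bd.merge_regions(labels, bands, threshold=0.05)
        assert len(np.unique(merged)) == 3

    def test_zero_threshold_is_identity(self):
        rng = np.random.default_rng(3)
        labels = bd.initial_watershed(rng.random((30, 30)), 9)
        bands = rng.random((3, 30, 30))
        merged = bd.merge_regions(labels, bands, threshold=0.0)
        assert np.array_equal(merged, labels)

    def test_huge_threshold_single_region(self):
        rng = np.random.default_rng(4)
        labels = bd.initial_watershed(rng.random((30, 30)), 9)
        merged = bd.merge_regions(labels, rng.random((3, 30, 30)), threshold=10.0)
        assert len(np.unique(merged)) == 1

    def test_region_count_monotone_in_threshold(self):
        rng = np.random.default_rng(5)
        labels = bd.initial_watershed(rng.random((40, 40)), 25)
        bands = rng.random((3, 40, 40))
        counts = [
            len(np.unique(bd.merge_regions(labels, bands, threshold=t)))
            for t in (0.0, 0.02, 0.05, 0.1, 0.5)
        ]
        assert counts == sorted(counts, reverse=True)


class TestProbabilityFilter:
    BOUNDS = (0.0, 0.0, 0.004, 0.004)

    def _labels(self):
        labels = np.ones((8, 8), dtype=int)
        labels[:, 4:] = 2
        return labels

    @pytest.mark.parametrize(
        "p_value,kept", [(0.6, True), (0.5, False), (0.49, False)]
    )
    def test_strict_threshold(self, p_value, kept):
        prob = np.full((8, 8), 0.2)
        prob[:, 4:] = p_value
        fields = bd.filter_by_probability(self._labels(), prob, self.BOUNDS)
        assert (len(fields) == 1) == kept
        for f in fields:
            assert f.mean_prob > 0.5

    def test_geometry_covers_the_region(self):
        prob = np.full((8, 8), 0.9)
        fields = bd.filter_by_probability(self._labels(), prob, self.BOUNDS)
        assert len(fields) == 2
        total = sum(f.geometry.area for f in fields)
        assert total == pytest.approx(0.004 * 0.004)


class TestRefine:
    def test_donut_hole_removed(self):
        outer = box(0, 0, 1e-3, 1e-3)
        inner = box(4e-4, 4e-4, 6e-4, 6e-4)
        donut = Polygon(outer.exterior.coords, [inner.exterior.coords])
        fields = bd.FieldPolygonSet(
            [bd.FieldPolygon("f", donut, bd.area_ha(donut), 0.9, ("t",))]
        )
        refined = bd.refine_polygons(fields, pixel_size=1e-4)
        assert refined.fields[0].geometry.area == pytest.approx(outer.area)

    def test_square_below_tolerance_unchanged(self):
        sq = box(0, 0, 1e-3, 1e-3)
        fields = bd.FieldPolygonSet(
            [bd.FieldPolygon("f", sq, bd.area_ha(sq), 0.9, ("t",))]
        )
        refined = bd.refine_polygons(fields, pixel_size=1e-5)
        assert refined.fields[0].geometry.equals(sq)

    def test_collinear_vertex_removed(self):
        poly = Polygon([(0, 0), (5e-4, 0), (1e-3, 0), (1e-3, 1e-3), (0, 1e-3)])
        fields = bd.FieldPolygonSet(
            [bd.FieldPolygon("f", poly, bd.area_ha(poly), 0.9, ("t",))]
        )
        refined = bd.refine_polygons(fields, pixel_size=1e-5)
        assert len(refined.fields[0].geometry.exterior.coords) == 5
        assert refined.fields[0].geometry.area == pytest.approx(poly.area)

    def test_visvalingam_keeps_high_area_vertices(self):
        ring = list(box(0, 0, 1, 1).exterior.coords)
        assert bd.visvalingam(ring, threshold=0.4) == ring


class TestSeams:
    PX = 1e-4

    def _field(self, geom, tile, fid="f"):
        return bd.FieldPolygon(fid, geom, bd.area_ha(geom), 0.8, (tile,))

    def test_split_field_unified_with_summed_area(self):
        left = box(0.0, 0.0, 0.05, 0.01)
        right = box(0.05, 0.0, 0.08, 0.01)
        merged = bd.merge_tile_seams(
            [
                bd.FieldPolygonSet([self._field(left, "t0")]),
                bd.FieldPolygonSet([self._field(right, "t1")]),
            ],
            self.PX,
        )
        assert len(merged) == 1
        assert merged.fields[0].geometry.area == pytest.approx(
            left.area + right.area
        )
        assert merged.fields[0].tiles == ("t0", "t1")

    def test_non_touching_fields_untouched(self):
        a = box(0.0, 0.0, 0.01, 0.01)
        b = box(0.06, 0.06, 0.07, 0.07)
        merged = bd.merge_tile_seams(
            [
                bd.FieldPolygonSet([self._field(a, "t0")]),
                bd.FieldPolygonSet([self._field(b, "t1")]),
            ],
            self.PX,
        )
        assert len(merged) == 2

    def test_idempotent(self):
        left = box(0.0, 0.0, 0.05, 0.01)
        right = box(0.05, 0.0, 0.08, 0.01)
        once = bd.merge_tile_seams(
            [
                bd.FieldPolygonSet([self._field(left, "t0")]),
                bd.FieldPolygonSet([self._field(right, "t1")]),
            ],
            self.PX,
        )
        twice = bd.merge_tile_seams([once], self.PX)
        assert len(twice) == len(once)
        assert twice.fields[0].geometry.equals(once.fields[0].geometry)


class TestSummaries:
    def test_mean_and_count_per_cell(self):
        spec = GridSpec()
        f1 = bd.FieldPolygon("a", box(0.01, 0.01, 0.02, 0.02), 1.0, 0.9, ("t",))
        f2 = bd.FieldPolygon("b", box(0.02, 0.03, 0.04, 0.04), 3.0, 0.9, ("t",))
        out = bd.summarize_fields(bd.FieldPolygonSet([f1, f2]), spec)
        assert out["tile_0_0"]["count"] == 2
        assert out["tile_0_0"]["mean_size_ha"] == pytest.approx(2.0)

    def test_counts_conserved_across_cells(self):
        spec = GridSpec()
        rng = np.random.default_rng(0)
        fields = []
        for k in range(25):
            cx, cy = rng.uniform(0.002, 0.148, 2)
            g = box(cx, cy, cx + 0.001, cy + 0.001)
            fields.append(bd.FieldPolygon(f"f{k}", g, bd.area_ha(g), 0.9, ("t",)))
        out = bd.summarize_fields(bd.FieldPolygonSet(fields), spec)
        assert sum(rec["count"] for rec in out.values()) == 25


def test_recovery_iou_and_count(segmentation_recovery):
    """On well-classified synthetic landscapes the delineation recovers the
    true cropland area (IoU) and the field count within +/-50%."""
    ious = [r["iou"] for r in segmentation_recovery]
    ratios = [r["count_ratio"] for r in segmentation_recovery]
    assert np.mean(ious) >= 0.7
    assert 0.5 <= np.mean(ratios) <= 1.5


def test_seam_invariance_one_tile_vs_two_halves():
    """Total retained field area agrees within 2% whether a landscape is
    segmented whole or as two half-tiles stitched back together."""
    from fieldmapper import learning as ln

    world = ln.make_demo_world(1, n_tiles=(1, 1))
    p = ndimage.uniform_filter(world.truth.astype(float), 5)
    params = bd.SegmentationParams(n_segments=256)
    whole, _ = bd.delineate_tile(
        world.composites["dry"], p, world.bounds, world.grid.pixel_size,
        "whole", params,
    )
    lon0, lat0, lon1, lat1 = world.bounds
    mid = world.truth.shape[1] // 2
    mid_lon = lon0 + (lon1 - lon0) / 2
    half_params = bd.SegmentationParams(n_segments=128)
    left, _ = bd.delineate_tile(
        world.composites["dry"][:, :, :mid], p[:, :mid],
        (lon0, lat0, mid_lon, lat1), world.grid.pixel_size, "L", half_params,
    )
    right, _ = bd.delineate_tile(
        world.composites["dry"][:, :, mid:], p[:, mid:],
        (mid_lon, lat0, lon1, lat1), world.grid.pixel_size, "R", half_params,
    )
    stitched = bd.merge_tile_seams([left, right], world.grid.pixel_size)
    assert stitched.total_area_ha() == pytest.approx(
        whole.total_area_ha(), rel=0.02
    )
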