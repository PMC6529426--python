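import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from oracles import flood_fill_count, opening_bruteforce, otsu_bruteforce
from thtquant.segmentation import (
    DegenerateHistogramError,
    FilterParams,
    LabeledObjects,
    ParameterError,
    _ball_element,
    binarize,
    label_objects,
    measure_objects,
    morphological_filter,
    otsu_threshold,
    remove_small_and_edge,
    rolling_ball_subtract,
)
from thtquant.segmentation import ObjectMeasurement


def image_from_values(values):
    values = np.asarray(values, np.uint8).ravel()
    side = int(np.ceil(np.sqrt(values.size)))
    padded = np.concatenate([values, np.repeat(values[-1], side * side - values.size)])
    return padded.reshape(side, side)


class TestOtsu:
    def test_bimodal_lowest_tie_break(self):
        img = image_from_values([10] * 8 + [200] * 8)
        assert otsu_threshold(img) == pytest.approx(10 / 255)

    def test_constant_image_degenerate(self):
        with pytest.raises(DegenerateHistogramError):
            otsu_threshold(np.full((4, 4), 128, np.uint8))

    def test_trimodal_matches_bruteforce(self):
        values = [50] * 100 + [150] * 50 + [250] * 50
        img = image_from_values(values)
        assert otsu_threshold(img) == pytest.approx(otsu_bruteforce(img) / 255)

    @settings(deadline=None, max_examples=40)
    @given(seed=st.integers(0, 2**31 - 1), n_levels=st.integers(2, 12))
    def test_random_histograms_match_bruteforce(self, seed, n_levels):
        r = np.random.default_rng(seed)
        levels = r.choice(256, size=n_levels, replace=False)
        values = np.repeat(levels, r.integers(1, 50, n_levels)).reshape(1, -1)
        assert otsu_threshold(values) == pytest.approx(otsu_bruteforce(values) / 255)


class TestBinarize:
    def test_zero_threshold_keeps_nonzero(self):
        img = np.array([[0, 1], [255, 0]], np.uint8)
        mask = binarize(img, 0.0)
        np.testing.assert_array_equal(mask.pixels, [[False, True], [True, False]])

    def test_unit_threshold_empty(self):
        img = np.array([[0, 255], [128, 3]], np.uint8)
        assert not binarize(img, 1.0).pixels.any()

    def test_strictly_greater_semantics(self):
        img = image_from_values([10] * 8 + [200] * 8)
        mask = binarize(img, 10 / 255)
        assert mask.pixels.sum() == 8
        assert (img[mask.pixels] == 200).all()

    def test_out_of_range_threshold(self):
        with pytest.raises(ParameterError):
            binarize(np.zeros((2, 2), np.uint8), 1.5)


class TestLabelObjects:
    def test_diagonal_connectivity(self):
        mask = np.zeros((4, 4), bool)
        mask[1, 1] = mask[2, 2] = True
        assert label_objects(mask, connectivity=4).n_objects == 2
        assert label_objects(mask, connectivity=8).n_objects == 1

    def test_empty_mask(self):
        out = label_objects(np.zeros((5, 5), bool))
        assert out.n_objects == 0 and (out.labels == 0).all()

    def test_raster_scan_label_order(self):
        mask = np.zeros((6, 6), bool)
        mask[4:6, 0:2] = True  # later in raster order
        mask[0:2, 3:5] = True  # earlier
        labels = label_objects(mask).labels
        assert labels[0, 3] == 1 and labels[4, 0] == 2

    @pytest.mark.parametrize("connectivity", [4, 8])
    def test_component_count_matches_flood_fill(self, rng, connectivity):
        mask = rng.random((64, 64)) < 0.35
        assert (
            label_objects(mask, connectivity).n_objects
            == flood_fill_count(mask, connectivity)
        )


class TestRemoveSmallAndEdge:
    def test_exactly_100px_retained(self):
        labels = np.zeros((20, 20), np.int32)
        labels[5:15, 5:15] = 1  # 100 px, interior
        out = remove_small_and_edge(LabeledObjects(labels, 1), FilterParams())
        assert out.n_objects == 1

    def test_99px_removed(self):
        labels = np.zeros((20, 20), np.int32)
        labels[5:14, 5:16] = 1  # 9 x 11 = 99 px
        assert (labels == 1).sum() == 99
        out = remove_small_and_edge(LabeledObjects(labels, 1), FilterParams())
        assert out.n_objects == 0

    def test_edge_touching_removed(self):
        labels = np.zeros((30, 30), np.int32)
        labels[0:20, 5:30] = 1  # 500 px but touches row 0 (and last column)
        out = remove_small_and_edge(LabeledObjects(labels, 1), FilterParams())
        assert out.n_objects == 0

    def test_constructed_scene_one_survivor(self):
        labels = np.zeros((40, 60), np.int32)
        labels[5:10, 5:15] = 1  # 50 px interior -> dropped (small)
        labels[15:25, 20:35] = 2  # 150 px interior -> kept
        labels[0:20, 40:60] = 3  # 400 px touching edges -> dropped
        out = remove_small_and_edge(LabeledObjects(labels, 3), FilterParams())
        assert out.n_objects == 1
        assert set(np.unique(out.labels)) == {0, 1}
        assert ((out.labels == 1) == (labels == 2)).all()


def square_scene(intensity=100, hole=False):
    img = np.zeros((14, 14), np.uint8)
    img[2:12, 2:12] = intensity
    labels = np.zeros((14, 14), np.int32)
    labels[2:12, 2:12] = 1
    if hole:
        img[6:8, 6:8] = 0
        labels[6:8, 6:8] = 0
    return img, LabeledObjects(labels, 1)


class TestMeasureObjects:
    def test_solid_square(self):
        img, objs = square_scene()
        (m,) = measure_objects(objs, img)
        assert m.area == 100
        assert m.perimeter == 36  # 4*10 - 4 corner-shared boundary pixels
        assert m.mean_intensity == pytest.approx(100.0)
        assert m.centroid == pytest.approx((6.5, 6.5))
        assert not m.touches_edge

    def test_holed_square_filled_before_measuring(self):
        img, objs = square_scene(hole=True)
        (m,) = measure_objects(objs, img)
        assert m.area == 100  # hole filled
        assert m.perimeter == 36
        assert m.mean_intensity == pytest.approx((96 * 100 + 4 * 0) / 100)

    def test_single_pixel(self):
        img = np.zeros((5, 5), np.uint8)
        img[2, 2] = 77
        labels = np.zeros((5, 5), np.int32)
        labels[2, 2] = 1
        (m,) = measure_objects(LabeledObjects(labels, 1), img)
        assert m.area == 1 and m.perimeter == 1
        assert m.mean_intensity == 77

    def test_edge_flag(self):
        img = np.zeros((10, 10), np.uint8)
        labels = np.zeros((10, 10), np.int32)
        labels[0:3, 4:7] = 1
        (m,) = measure_objects(LabeledObjects(labels, 1), img)
        assert m.touches_edge

    def test_area_equals_pixel_count_without_holes(self, rng):
        from scipy import ndimage as ndi

        # hole-free random blobs: fill any holes before labeling
        filled = ndi.binary_fill_holes(ndi.binary_closing(rng.random((40, 40)) < 0.3))
        objs = label_objects(filled, connectivity=8)
        counts = np.bincount(objs.labels.ravel(), minlength=objs.n_objects + 1)
        for m in measure_objects(objs, np.zeros_like(filled, np.uint8)):
            assert m.area == counts[m.object_id]


class TestMorphologicalFilter:
    @pytest.mark.parametrize(
        "area,perimeter,kept",
        [
            (299, 80, False),
            (300, 80, True),
            (1000, 80, True),
            (1001, 80, False),
            (500, 164, True),
            (500, 165, True),
            (500, 166, False),
        ],
    )
    def test_printed_boundaries(self, area, perimeter, kept):
        m = ObjectMeasurement(1, area, perimeter, 100.0, False, (0.0, 0.0))
        table = morphological_filter([m], FilterParams())
        assert (table.n_cells == 1) is kept

    def test_survivors_match_direct_predicate(self, rng):
        ms = [
            ObjectMeasurement(
                i,
                int(rng.integers(50, 1400)),
                int(rng.integers(30, 250)),
                float(rng.uniform(0, 255)),
                False,
                (0.0, 0.0),
            )
            for i in range(10)
        ]
        params = FilterParams()
        table = morphological_filter(ms, params)
        expected = [m for m in ms if 300 <= m.area <= 1000 and m.perimeter <= 165]
        assert table.rows == expected

    @settings(deadline=None, max_examples=30)
    @given(
        seed=st.integers(0, 2**31 - 1),
        amin=st.integers(300, 500),
        amax=st.integers(500, 1000),
        pmax=st.integers(100, 165),
    )
    def test_shrinking_window_is_monotone(self, seed, amin, amax, pmax):
        r = np.random.default_rng(seed)
        ms = [
            ObjectMeasurement(i, int(r.integers(50, 1400)), int(r.integers(30, 250)),
                              100.0, False, (0.0, 0.0))
            for i in range(30)
        ]
        wide = morphological_filter(ms, FilterParams())
        narrow = morphological_filter(
            ms, FilterParams(area_min=amin, area_max=amax, perimeter_max=pmax)
        )
        assert narrow.n_cells <= wide.n_cells
        assert set(id(m) for m in narrow.rows) <= set(id(m) for m in wide.rows)

    def test_relabeling_stability(self, rng):
        """Survivor measurements do not depend on original label numbering."""
        img = np.zeros((60, 90), np.uint8)
        labels = np.zeros((60, 90), np.int32)
        img[10:30, 10:30] = 120
        labels[10:30, 10:30] = 1
        img[35:55, 40:60] = 90
        labels[35:55, 40:60] = 2
        permuted = np.zeros_like(labels)
        permuted[labels == 1] = 2
        permuted[labels == 2] = 1
        a = measure_objects(LabeledObjects(labels, 2), img)
        b = measure_objects(LabeledObjects(permuted, 2), img)
        key = lambda m: m.centroid
        for ma, mb in zip(sorted(a, key=key), sorted(b, key=key)):
            assert (ma.area, ma.perimeter, ma.mean_intensity) == (
                mb.area, mb.perimeter, mb.mean_intensity
            )


class TestRollingBall:
    def test_flat_background_maps_to_zero(self):
        out = rolling_ball_subtract(np.full((40, 40), 50.0), radius=20)
        np.testing.assert_allclose(out, 0.0, atol=1e-9)

    def test_small_plateau_retained(self):
        img = np.full((60, 60), 50.0)
        img[30:33, 30:33] += 100.0
        out = rolling_ball_subtract(img, radius=20)
        assert out[31, 31] >= 95.0
        assert abs(out[5, 5]) < 1e-9

    def test_peak_on_ramp_preserved(self):
        ramp = np.tile(np.linspace(10, 40, 48), (48, 1))
        img = ramp.copy()
        img[20:23, 20:23] += 80.0
        out = rolling_ball_subtract(img, radius=20)
        assert out[21, 21] == pytest.approx(80.0, rel=0.05)

    def test_matches_bruteforce_opening(self, rng):
        img = rng.integers(0, 256, (24, 24)).astype(float)
        radius = 5
        footprint, heights = _ball_element(radius)
        background = opening_bruteforce(img, footprint, heights)
        out = rolling_ball_subtract(img, radius=radius)
        np.testing.assert_allclose(out, np.clip(img - background, 0, None), atol=1e-9)

    def test_radius_larger_than_image(self):
        with pytest.raises(ParameterError):
            rolling_ball_subtract(np.zeros((8, 8)), radius=20)
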