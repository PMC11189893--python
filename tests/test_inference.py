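"""Map prediction, thresholding, watershed assembly and region tables."""

import numpy as np
import pytest

from bbseg.inference import (
    Segmentation,
    binarize,
    predict_maps,
    region_table,
    watershed_split,
)
from bbseg.labels import edge_distance
from bbseg.network import NetworkSpec, build
from bbseg.params import ParamSet
from bbseg.sampling import extract_stack, normalize_image


class TestBinarize:
    def test_threshold_is_inclusive(self):
        pmap = np.array([[0.49, 0.5, 0.51]])
        assert binarize(pmap, 0.5).tolist() == [[False, True, True]]

    def test_count_conservation(self, rng):
        pmap = rng.uniform(size=(30, 30))
        assert binarize(pmap, 0.3).sum() == (pmap >= 0.3).sum()

    def test_threshold_range_enforced(self):
        with pytest.raises(ValueError):
            binarize(np.zeros((2, 2)), 1.0)


def _touching_disks(h=60, w=100):
    """Two disks tangent along a vertical contact; returns the label map."""
    yy, xx = np.mgrid[0:h, 0:w]
    lab = np.zeros((h, w), np.int32)
    d1 = np.hypot(yy - 30, xx - 35)
    d2 = np.hypot(yy - 30, xx - 64)
    r = 15.0
    lab[(d1 <= r) & (d1 <= d2)] = 1
    lab[(d2 <= r) & (d2 < d1)] = 2
    return lab


class TestWatershed:
    def test_ideal_maps_recover_touching_disks(self):
        truth = _touching_disks()
        dmap = edge_distance(truth, 10)
        binary = truth > 0
        seg = watershed_split(binary, dmap, ParamSet())
        assert seg.n_regions == 2
        # away from a 1-px contact band the partition matches the truth
        contact = np.zeros_like(binary)
        from scipy import ndimage

        d1 = ndimage.binary_dilation(truth == 1, iterations=2)
        d2 = ndimage.binary_dilation(truth == 2, iterations=2)
        contact = d1 & d2
        interior = binary & ~contact
        # map predicted ids to truth ids by majority overlap
        agree = 0
        for tid in (1, 2):
            pid = np.bincount(seg.labels[(truth == tid) & interior]).argmax()
            agree += ((seg.labels == pid) & (truth == tid) & interior).sum()
        assert agree == interior.sum()

    def test_single_blob_covered_exactly(self):
        lab = np.zeros((40, 40), np.int32)
        lab[10:30, 8:28] = 1
        dmap = edge_distance(lab, 10)
        seg = watershed_split(lab > 0, dmap, ParamSet())
        assert seg.n_regions == 1
        assert np.array_equal(seg.labels > 0, lab > 0)

    def test_every_foreground_pixel_labeled_or_filtered(self, rng):
        from conftest import random_label_map

        for _ in range(5):
            truth = random_label_map(rng)
            binary = truth > 0
            dmap = edge_distance(truth, 10)
            params = ParamSet(min_region_px=0)
            seg = watershed_split(binary, dmap, params)
            assert np.array_equal(seg.labels > 0, binary)

    def test_small_regions_removed(self):
        lab = np.zeros((30, 30), np.int32)
        lab[2:4, 2:4] = 1  # 4 px, below min_region_px=10
        lab[10:25, 10:25] = 2
        dmap = edge_distance(lab, 10)
        seg = watershed_split(lab > 0, dmap, ParamSet())
        assert seg.n_regions == 1

    def test_no_markers_warns_and_returns_empty(self):
        binary = np.zeros((10, 10), bool)
        with pytest.warns(UserWarning, match="markers"):
            seg = watershed_split(binary, np.zeros((10, 10)), ParamSet())
        assert seg.n_regions == 0

    def test_labels_renumbered_in_raster_order(self):
        truth = _touching_disks()
        seg = watershed_split(truth > 0, edge_distance(truth, 10), ParamSet())
        firsts = [np.argmax((seg.labels == k).ravel()) for k in (1, 2)]
        assert firsts[0] < firsts[1]

    def test_rerun_identical(self):
        truth = _touching_disks()
        dmap = edge_distance(truth, 10)
        a = watershed_split(truth > 0, dmap, ParamSet())
        b = watershed_split(truth > 0, dmap, ParamSet())
        assert np.array_equal(a.labels, b.labels)


class TestRegionTable:
    def test_empty_segmentation_gives_empty_table(self):
        table = region_table(Segmentation(labels=np.zeros((5, 5), np.int32)))
        assert len(table) == 0

    def test_areas_sum_to_foreground(self, rng):
        from conftest import random_label_map

        lab = random_label_map(rng)
        table = region_table(Segmentation(labels=lab))
        assert table["area"].sum() == (lab > 0).sum()

    def test_disk_centroid_is_its_center(self):
        lab = np.zeros((41, 41), np.int32)
        yy, xx = np.mgrid[0:41, 0:41]
        lab[np.hypot(yy - 20, xx - 20) <= 10] = 1
        table = region_table(Segmentation(labels=lab))
        assert abs(table.loc[0, "centroid_row"] - 20) <= 0.5
        assert abs(table.loc[0, "centroid_col"] - 20) <= 0.5


@pytest.fixture(scope="module")
def net():
    return build(NetworkSpec(n_channels=2), seed=4)


@pytest.fixture(scope="module")
def params():
    return ParamSet(scales=(1, 3))


class TestPredictMaps:
    def test_aoi_excluded_pixels_are_zero(self, net, params, rng):
        img = rng.uniform(0, 255, (20, 20))
        aoi = np.zeros((20, 20), bool)
        aoi[5:15, 5:15] = True
        pmap, dmap = predict_maps(net, img, aoi, params)
        assert not pmap[~aoi].any() and not dmap[~aoi].any()
        assert pmap.shape == img.shape == dmap.shape

    def test_matches_per_pixel_loop_oracle(self, net, params, rng):
        img = rng.uniform(0, 255, (12, 12))
        pmap, dmap = predict_maps(net, img, None, params)
        norm = normalize_image(img)
        for r in range(0, 12, 3):
            for c in range(0, 12, 3):
                stack = extract_stack(norm, (r, c), params.scales, 25)
                p, d = net.predict(stack)
                assert abs(pmap[r, c] - p[0]) < 1e-4
                assert abs(dmap[r, c] - np.clip(d[0], 0, params.dist_cap)) < 1e-4

    def test_distance_clipped_to_cap(self, net, params, rng):
        img = rng.uniform(0, 255, (15, 15))
        _, dmap = predict_maps(net, img, None, params)
        assert dmap.min() >= 0 and dmap.max() <= params.dist_cap

    def test_repeat_runs_identical(self, net, params, rng):
        img = rng.uniform(0, 255, (16, 16))
        a = predict_maps(net, img, None, params)
        b = predict_maps(net, img, None, params)
        assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])
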