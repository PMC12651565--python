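"""Segmentation chain: grayscale conversion, Otsu binarization against an
exhaustive oracle, closing, watershed fixtures, and region extraction."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ctcscan import segmentation as seg
from conftest import disk_mask


def exhaustive_otsu(img):
    """Independent oracle: per-level loop maximizing between-class variance
    of the split {<= t} vs {> t}; lowest maximizing level."""
    img = np.rint(img).astype(int).ravel()
    best_t, best_v = 0, -1.0
    for t in range(256):
        lo = img[img <= t]
        hi = img[img > t]
        if len(lo) == 0 or len(hi) == 0:
            continue
        w0, w1 = len(lo), len(hi)
        v = w0 * w1 * (lo.mean() - hi.mean()) ** 2
        if v > best_v + 1e-9:
            best_v, best_t = v, t
    return best_t


class TestToGrayscale:
    def test_constant_8bit_passthrough(self):
        img = np.full((5, 5), 40, np.uint8)
        assert np.allclose(seg.to_grayscale(img), 40.0)

    def test_16bit_scales_to_255(self):
        img = np.zeros((4, 4), np.uint16)
        img[0, 0] = 65535
        out = seg.to_grayscale(img)
        assert out.max() == pytest.approx(255.0)

    def test_gray_rgb_identity(self):
        v = 123
        img = np.full((6, 6, 3), v, np.uint8)
        assert np.allclose(seg.to_grayscale(img), v, atol=0.5)

    def test_unsupported_ndim(self):
        with pytest.raises(ValueError):
            seg.to_grayscale(np.zeros((2, 2, 2, 2)))


class TestBinarize:
    def test_otsu_matches_exhaustive_oracle_on_random_images(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            img = rng.integers(0, 256, size=(24, 24)).astype(np.uint8)
            assert seg.otsu_threshold(img) == exhaustive_otsu(img)

    def test_perfectly_bimodal_foreground(self):
        rng = np.random.default_rng(1)
        img = np.where(rng.random((50, 50)) < 0.9, 10, 200).astype(np.uint8)
        mask = seg.binarize(img)
        assert np.array_equal(mask, img == 200)

    def test_fixed_threshold_on_ramp(self):
        img = np.tile(np.arange(256, dtype=np.uint8), (4, 1))
        mask = seg.binarize(img, method="fixed", fixed_value=128)
        assert mask.mean() == pytest.approx((img > 128).mean())

    def test_constant_image_warns_and_returns_empty(self):
        img = np.full((10, 10), 50, np.uint8)
        with pytest.warns(UserWarning, match="constant"):
            mask = seg.binarize(img, method="otsu")
        assert not mask.any()


class TestCloseMask:
    def test_zero_iterations_identity(self):
        rng = np.random.default_rng(2)
        mask = rng.random((30, 30)) > 0.5
        assert np.array_equal(seg.close_mask(mask, iterations=0), mask)

    def test_three_iterations_fill_3px_hole(self):
        mask = disk_mask((60, 60), (30, 30), 15)
        hole = disk_mask((60, 60), (30, 30), 1.5)
        assert hole.sum() >= 5
        out = seg.close_mask(mask & ~hole, iterations=3)
        assert out[hole].all()

    def test_closing_is_extensive_on_random_masks(self):
        rng = np.random.default_rng(3)
        for _ in range(100):
            mask = rng.random((32, 32)) > rng.uniform(0.4, 0.9)
            out = seg.close_mask(mask, iterations=3)
            assert (out | mask).sum() == out.sum()  # out ⊇ mask


class TestWatershed:
    def test_single_disk_one_region(self):
        mask = disk_mask((80, 80), (40, 40), 18)
        labels = seg.watershed_split(mask)
        assert labels.max() == 1

    def test_two_overlapping_disks_split_in_two(self):
        mask = disk_mask((100, 100), (50, 35), 20) | \
            disk_mask((100, 100), (50, 65), 20)
        labels = seg.watershed_split(mask)
        assert labels.max() == 2
        # split boundary lies between the two centers
        assert labels[50, 35] != labels[50, 65]

    def test_fifty_random_disks_counted_exactly(self):
        rng = np.random.default_rng(4)
        shape = (600, 600)
        mask = np.zeros(shape, bool)
        centers = []
        while len(centers) < 50:
            cy, cx = rng.uniform(15, 585, size=2)
            if all((cy - y) ** 2 + (cx - x) ** 2 > (26. ** 2)
                   for y, x in centers):
                centers.append((cy, cx))
                mask |= disk_mask(shape, (cy, cx), rng.uniform(6, 12))
        labels = seg.watershed_split(mask)
        assert labels.max() == 50

    def test_empty_mask_empty_labelling(self):
        labels = seg.watershed_split(np.zeros((20, 20), bool))
        assert labels.max() == 0

    def test_label_conservation(self):
        mask = disk_mask((90, 90), (40, 30), 15) | \
            disk_mask((90, 90), (50, 60), 12)
        labels = seg.watershed_split(mask)
        assert (labels > 0).sum() == mask.sum()


class TestExtractRegions:
    def test_empty_labelling_empty_list(self):
        assert seg.extract_regions(np.zeros((10, 10), np.int32), 0.377) == []

    def test_single_region_area(self):
        labels = np.zeros((20, 20), np.int32)
        labels[5:15, 5:15] = 1
        regions = seg.extract_regions(labels, 1.0, area_min_um2=1,
                                      area_max_um2=1e9)
        assert len(regions) == 1
        assert regions[0].area_px == 100

    def test_area_filter_in_micrometres(self):
        # pixel size 1 µm → px areas equal µm² areas
        labels = np.zeros((200, 200), np.int32)
        labels[2:4, 2:4] = 1            # 4 px
        labels[10:30, 10:30] = 2        # 400 px
        labels[60:180, 60:150] = 3      # 10800 px
        regions = seg.extract_regions(labels, 1.0, area_min_um2=50,
                                      area_max_um2=5000)
        assert [r.area_px for r in regions] == [400]


def test_translation_equivariance(small_config):
    import ctcscan as cs
    cfg = cs.SimulationConfig(image_height_px=220, image_width_px=220,
                              n_background_cells=6)
    scan, _ = cs.simulate_scan(cfg, 17)
    dapi = scan.channels["DAPI"]
    pad = np.zeros((260, 260), dapi.dtype)
    pad[:220, :220] = dapi
    shifted = np.roll(np.roll(pad, 13, axis=0), 23, axis=1)
    _, r0 = seg.segment_dapi(pad, cfg.pixel_size_um)
    _, r1 = seg.segment_dapi(shifted, cfg.pixel_size_um)
    c0 = sorted((r.centroid for r in r0))
    c1 = sorted(((r.centroid[0] - 13, r.centroid[1] - 23) for r in r1))
    assert len(c0) == len(c1)
    for (a, b), (c, d) in zip(c0, c1):
        assert a == pytest.approx(c, abs=1e-6)
        assert b == pytest.approx(d, abs=1e-6)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(st.integers(0, 2 ** 31 - 1))
def test_segmentation_conserves_foreground_pixels(seed):
    """Sum of watershed region areas equals the closed-mask pixel count."""
    rng = np.random.default_rng(seed)
    mask = np.zeros((80, 80), bool)
    for _ in range(rng.integers(0, 5)):
        cy, cx = rng.uniform(10, 70, 2)
        mask |= disk_mask((80, 80), (cy, cx), rng.uniform(3, 9))
    closed = seg.close_mask(mask)
    labels = seg.watershed_split(closed)
    assert (labels > 0).sum() == closed.sum()
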