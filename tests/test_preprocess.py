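"""Unit and property tests for the morphological preprocessing chain."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from paniclecount.preprocess import (DegenerateHistogramError,
                                     PreprocessConfig, apply_mask, dilate,
                                     disk_element, erode, otsu_threshold,
                                     preprocess_image,
                                     remove_small_components, remove_stem,
                                     to_grayscale)
from paniclecount.synthetic import SyntheticSpec, render_panicle

from conftest import random_blob_mask
from oracles import (area_filter, exhaustive_otsu, max_filter_dilate,
                     min_filter_erode)


class TestGrayscale:
    def test_equal_channels_pass_through(self):
        img = np.full((4, 5, 3), 100, dtype=np.uint8)
        assert (to_grayscale(img) == 100).all()

    def test_pure_red_luma(self):
        img = np.zeros((1, 1, 3), dtype=np.uint8)
        img[0, 0] = (255, 0, 0)
        assert to_grayscale(img)[0, 0] == 76  # round(0.299 * 255)

    def test_black_stays_black(self):
        assert (to_grayscale(np.zeros((3, 3, 3), dtype=np.uint8)) == 0).all()

    def test_rejects_non_rgb(self):
        with pytest.raises(ValueError):
            to_grayscale(np.zeros((4, 4), dtype=np.uint8))


class TestOtsu:
    def test_bimodal_halves(self):
        gray = np.full((10, 10), 10, dtype=np.uint8)
        gray[:, 5:] = 200
        t, mask = otsu_threshold(gray)
        assert (mask == (gray == 200)).all()
        assert 10 <= t < 200

    def test_two_pixel_extremes(self):
        gray = np.array([[0, 255]], dtype=np.uint8)
        _, mask = otsu_threshold(gray)
        assert mask.tolist() == [[False, True]]

    def test_constant_image_is_degenerate(self):
        with pytest.raises(DegenerateHistogramError):
            otsu_threshold(np.full((5, 5), 42, dtype=np.uint8))

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_exhaustive_search_on_random_images(self, seed):
        r = np.random.default_rng(seed)
        gray = np.clip(
            np.concatenate([r.normal(40, 12, 600), r.normal(180, 25, 400)]),
            0, 255,
        ).astype(np.uint8).reshape(40, 25)
        t, _ = otsu_threshold(gray)
        assert t == exhaustive_otsu(gray)

    def test_covers_synthetic_grain_pixels(self, small_panicle, small_cfg):
        gray = to_grayscale(small_panicle.image)
        _, mask = otsu_threshold(gray)
        truth = small_panicle.grain_mask
        assert (mask & truth).sum() / truth.sum() >= 0.99


class TestComponentFilter:
    @staticmethod
    def _three_components():
        mask = np.zeros((80, 80), dtype=bool)
        mask[1:4, 1:4] = True          # area 9
        mask[10:20, 10:30] = True      # area 200
        mask[35:75, 35:75] = True      # area 1600
        return mask

    def test_keeps_large_only(self):
        out = remove_small_components(self._three_components(), 1000)
        assert out.sum() == 1600 and out[35:75, 35:75].all()

    def test_threshold_is_inclusive(self):
        out = remove_small_components(self._three_components(), 200)
        assert out.sum() == 1800  # the 200-px component is kept

    def test_empty_mask(self):
        assert remove_small_components(np.zeros((5, 5), bool), 10).sum() == 0

    @pytest.mark.parametrize("connectivity", [4, 8])
    @pytest.mark.parametrize("seed", range(8))
    def test_matches_flood_fill_oracle(self, seed, connectivity):
        mask = random_blob_mask(seed)
        ours = remove_small_components(mask, 5, connectivity)
        assert (ours == area_filter(mask, 5, connectivity)).all()

    def test_idempotent_and_antiextensive(self):
        mask = random_blob_mask(99)
        once = remove_small_components(mask, 8)
        assert once.sum() <= mask.sum()
        assert (remove_small_components(once, 8) == once).all()


class TestDiskElement:
    def test_5x5_disk_excludes_corners(self):
        el = disk_element(5)
        assert el.sum() == 21
        assert not el[0, 0] and not el[0, 4] and not el[4, 0] and not el[4, 4]
        assert el[0, 1] and el[2, 2]

    def test_rejects_even_diameter(self):
        with pytest.raises(ValueError):
            disk_element(4)


class TestErodeDilate:
    def test_square_erosion_shrinks_by_radius(self):
        mask = np.zeros((60, 60), dtype=bool)
        mask[5:55, 5:55] = True  # 50x50 solid square
        out = erode(mask, 5, 1)
        expected = np.zeros_like(mask)
        expected[7:53, 7:53] = True  # 46x46, verified pixel-by-pixel below
        assert (out == expected).all()
        assert (out == min_filter_erode(mask, disk_element(5))).all()

    def test_zero_iterations_is_identity(self):
        mask = random_blob_mask(3)
        assert (erode(mask, 5, 0) == mask).all()
        assert (dilate(mask, 5, 0) == mask).all()

    def test_thin_line_annihilated(self):
        mask = np.zeros((20, 40), dtype=bool)
        mask[8:11, 2:38] = True  # 3 px wide
        assert erode(mask, 5, 1).sum() == 0

    def test_single_pixel_dilates_to_element(self):
        mask = np.zeros((9, 9), dtype=bool)
        mask[4, 4] = True
        out = dilate(mask, 5, 1)
        assert (out[2:7, 2:7] == disk_element(5)).all()
        assert out.sum() == 21

    def test_empty_mask_stays_empty(self):
        assert dilate(np.zeros((6, 6), bool), 5, 2).sum() == 0

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_min_max_filter_oracles(self, seed):
        mask = random_blob_mask(seed, density=0.5)
        el = disk_element(5)
        assert (erode(mask, 5, 1) == min_filter_erode(mask, el)).all()
        assert (dilate(mask, 5, 1) == max_filter_dilate(mask, el)).all()

    @pytest.mark.parametrize("seed", range(4))
    def test_adjunction_properties(self, seed):
        mask = random_blob_mask(seed, density=0.6)
        er, di = erode(mask, 5, 2), dilate(mask, 5, 2)
        assert (er <= mask).all() and (di >= mask).all()
        opening = dilate(er, 5, 2)
        assert (opening <= mask).all()

    def test_opening_is_idempotent(self):
        mask = random_blob_mask(17, density=0.6)
        op1 = dilate(erode(mask, 5, 1), 5, 1)
        op2 = dilate(erode(op1, 5, 1), 5, 1)
        assert (op1 == op2).all()


@settings(max_examples=30, derandomize=True, deadline=None)
@given(arrays(np.bool_, (16, 16), elements=st.booleans()))
def test_morphology_invariants_hold_on_arbitrary_masks(mask):
    """Opening is anti-extensive and the area filter is a monotone,
    idempotent shrinker on any mask whatsoever."""
    opened = dilate(erode(mask, 3, 1), 3, 1)
    assert (opened <= mask).all()
    filtered = remove_small_components(mask, 3)
    assert (filtered <= mask).all()
    assert (remove_small_components(filtered, 3) == filtered).all()


class TestRemoveStem:
    def test_thick_structures_untouched(self):
        mask = np.zeros((60, 60), dtype=bool)
        mask[10:50, 10:50] = True
        stemless, stem, opened = remove_stem(mask, PreprocessConfig())
        assert stem.sum() == 0
        assert (stemless == mask).all()
        assert (opened <= mask).all()

    def test_thin_line_becomes_stem(self):
        mask = np.zeros((40, 70), dtype=bool)
        mask[17:23, 5:65] = True  # 6 px wide, area 360 >= 200
        stemless, stem, _ = remove_stem(mask, PreprocessConfig())
        assert (stem == mask).all()
        assert stemless.sum() == 0

    def test_partition_invariants_on_synthetic(self, small_panicle, small_cfg):
        res = preprocess_image(small_panicle.image, small_cfg)
        assert not (res.stemless_mask & res.stem_mask).any()
        assert ((res.stemless_mask | res.stem_mask) <= res.denoised_mask).all()
        assert (res.opened_mask <= res.denoised_mask).all()

    def test_recovers_stem_and_keeps_grains(self):
        # 40 px grains on a 6 px stem/rachis: the opening isolates the stem
        spec = SyntheticSpec(
            image_size=(560, 1500), n_grains=12, grain_width_px=(38.0, 42.0),
            stem_width_px=(6.0, 6.0), shape="B", n_branches=2, n_speckles=0,
            overlap_prob=0.3, seed=5,
        )
        pan = render_panicle(spec)
        res = preprocess_image(pan.image, PreprocessConfig())
        stem_truth = pan.stem_mask
        grain_truth = pan.grain_mask
        assert (res.stem_mask & stem_truth).sum() / stem_truth.sum() >= 0.90
        assert (res.stemless_mask & grain_truth).sum() / grain_truth.sum() >= 0.95


class TestApplyMask:
    def test_full_and_empty_masks(self):
        img = np.arange(2 * 3 * 3, dtype=np.uint8).reshape(2, 3, 3)
        assert (apply_mask(img, np.ones((2, 3), bool)) == img).all()
        assert apply_mask(img, np.zeros((2, 3), bool)).sum() == 0

    def test_half_mask_pixel_counts(self):
        img = np.full((4, 4, 3), 7, dtype=np.uint8)
        mask = np.zeros((4, 4), bool)
        mask[:, :2] = True
        out = apply_mask(img, mask)
        assert (out[:, :2] == 7).all() and (out[:, 2:] == 0).all()

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError):
            apply_mask(np.zeros((4, 4, 3), np.uint8), np.zeros((3, 3), bool))


class TestFullChain:
    def test_speckles_removed_in_denoised(self, small_cfg):
        spec = SyntheticSpec(seed=21, n_speckles=30).at_scale(0.25)
        pan = render_panicle(spec)
        res = preprocess_image(pan.image, small_cfg)
        # everything surviving denoise must belong to the panicle, not fabric
        import scipy.ndimage as ndi
        panicle_zone = ndi.binary_dilation(
            pan.grain_mask | pan.stem_mask | pan.rachis_mask, iterations=3
        )
        stray = res.denoised_mask & ~panicle_zone
        assert stray.sum() == 0

    def test_no_stem_no_noise_image_passes_through(self, small_cfg):
        spec = SyntheticSpec(
            seed=13, n_grains=60, n_speckles=0, stem_debris=(0, 0),
            draw_rachis=False,
        ).at_scale(0.25)
        pan = render_panicle(spec)
        res = preprocess_image(pan.image, small_cfg)
        diff = (res.stemless_mask ^ res.raw_mask).sum()
        assert diff / res.raw_mask.size < 0.01

    def test_deterministic(self, small_panicle, small_cfg):
        a = preprocess_image(small_panicle.image, small_cfg)
        b = preprocess_image(small_panicle.image, small_cfg)
        assert a.otsu_threshold == b.otsu_threshold
        assert (a.stemless_mask == b.stemless_mask).all()
        assert (a.masked_rgb == b.masked_rgb).all()

    def test_stem_removal_flag_off(self, small_panicle):
        cfg = PreprocessConfig(remove_stem=False).at_scale(0.25)
        res = preprocess_image(small_panicle.image, cfg)
        assert res.stem_mask.sum() == 0
        assert (res.stemless_mask == res.denoised_mask).all()

    def test_scaled_config_values(self):
        cfg = PreprocessConfig().at_scale(0.25)
        assert cfg.denoise_min_area == 62
        assert cfg.stem_min_area == 12
        assert cfg.erode_iterations == 1 and cfg.dilate_iterations == 1
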