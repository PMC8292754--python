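"""Baseline segmentation: blur formula, shape filters, mask extraction."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from skimage import measure

from spotid.baseline import (BaselineConfig, evaluate_segmentation,
                             extract_fish_mask_baseline,
                             extract_spots_baseline, filter_spot_regions,
                             spot_blur_sigma)
from spotid.errors import EmptyMaskError, NoSubjectFoundError


class TestSpotBlurSigma:
    @pytest.mark.parametrize("length,expected", [
        (1882, 19.0),
        (2322, 21.0),
        (5184, 34.00909090909091),
    ])
    def test_formula_values(self, length, expected):
        assert spot_blur_sigma(length) == pytest.approx(expected, abs=1e-9)

    def test_clamped_below(self):
        # the affine formula stays above 10 for positive lengths, so the
        # clamp only matters when a larger floor is requested
        assert spot_blur_sigma(100) == pytest.approx(10.9)
        assert spot_blur_sigma(100, sigma_min=12.0) == 12.0

    def test_rejects_nonpositive_length(self):
        with pytest.raises(ValueError):
            spot_blur_sigma(0)

    @given(st.floats(min_value=1882, max_value=20000),
           st.floats(min_value=1882, max_value=20000))
    def test_affine_and_increasing_above_clamp(self, a, b):
        lo, hi = sorted((a, b))
        assert spot_blur_sigma(hi) >= spot_blur_sigma(lo)
        # affine: slope is constant 2/440
        assert spot_blur_sigma(hi) - spot_blur_sigma(lo) == pytest.approx(
            (hi - lo) * 2 / 440, rel=1e-9, abs=1e-9)


class TestFilterSpotRegions:
    @staticmethod
    def _labels_of(mask):
        return measure.label(mask)

    def test_moderate_disc_kept(self):
        mask = np.zeros((100, 100), bool)
        yy, xx = np.mgrid[0:100, 0:100]
        mask |= (xx - 50) ** 2 + (yy - 50) ** 2 <= 8**2
        cfg = BaselineConfig()
        out = filter_spot_regions(self._labels_of(mask), body_area=1e5,
                                  cfg=cfg)
        assert (out > 0).sum() == mask.sum()

    def test_single_pixel_removed(self):
        mask = np.zeros((50, 50), bool)
        mask[10, 10] = True
        out = filter_spot_regions(self._labels_of(mask), body_area=1e6,
                                  cfg=BaselineConfig())
        assert not (out > 0).any()

    def test_elongated_bar_removed_by_circularity(self):
        # 40x2 bar: circularity 4*pi*80/perimeter^2 well below 0.5
        mask = np.zeros((60, 60), bool)
        mask[30:32, 10:50] = True
        out = filter_spot_regions(self._labels_of(mask), body_area=2e4,
                                  cfg=BaselineConfig())
        assert not (out > 0).any()

    def test_idempotent(self):
        rng = np.random.default_rng(0)
        mask = np.zeros((120, 120), bool)
        yy, xx = np.mgrid[0:120, 0:120]
        for _ in range(6):
            x, y, r = rng.uniform(10, 110), rng.uniform(10, 110), \
                rng.uniform(1, 9)
            mask |= (xx - x) ** 2 + (yy - y) ** 2 <= r**2
        cfg = BaselineConfig()
        once = filter_spot_regions(self._labels_of(mask), 3e4, cfg)
        twice = filter_spot_regions(once, 3e4, cfg)
        assert (once == twice).all()


class TestEvaluateSegmentation:
    def test_perfect_prediction(self):
        m = np.zeros((10, 10), bool)
        m[2:5, 2:5] = True
        assert evaluate_segmentation(m, m) == (1.0, 1.0, 1.0)

    def test_empty_prediction_convention(self):
        truth = np.ones((4, 4), bool)
        pred = np.zeros((4, 4), bool)
        assert evaluate_segmentation(pred, truth) == (0.0, 0.0, 0.0)

    def test_half_overlap(self):
        pred = np.zeros((10, 10), bool)
        truth = np.zeros((10, 10), bool)
        pred[0:2, 0:10] = True          # 20 px
        truth[1:3, 0:10] = True         # 20 px, overlap 10
        p, r, f = evaluate_segmentation(pred, truth)
        assert (p, r, f) == (0.5, 0.5, 0.5)

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            evaluate_segmentation(np.zeros((3, 3), bool),
                                  np.zeros((4, 4), bool))


class TestExtractFishMask:
    def test_uniform_white_image_has_no_subject(self):
        img = np.full((200, 300, 3), 255, np.uint8)
        with pytest.raises(NoSubjectFoundError):
            extract_fish_mask_baseline(img, BaselineConfig.for_image_size(300))

    def test_centred_blob_selected_over_larger_offcentre(self):
        img = np.full((300, 300), 220.0)
        yy, xx = np.mgrid[0:300, 0:300]
        img[(xx - 150) ** 2 + (yy - 150) ** 2 <= 40**2] = 20   # centred
        img[(xx - 40) ** 2 + (yy - 40) ** 2 <= 60**2] = 20     # larger corner
        cfg = BaselineConfig(sigma1=3, erosion_radius=2)
        mask = extract_fish_mask_baseline(img, cfg)
        ys, xs = np.nonzero(mask)
        assert abs(ys.mean() - 150) < 10 and abs(xs.mean() - 150) < 10

    def test_body_f1_on_default_render(self, default_render):
        img, body, _ = default_render
        cfg = BaselineConfig.for_image_size(max(img.shape[:2]))
        pred = extract_fish_mask_baseline(img, cfg)
        _, _, f1 = evaluate_segmentation(pred, body)
        assert f1 >= 0.90


class TestExtractSpots:
    def test_spots_inside_body_only(self, default_render):
        img, body, _ = default_render
        cfg = BaselineConfig.for_image_size(max(img.shape[:2]))
        pred_body = extract_fish_mask_baseline(img, cfg)
        spots = extract_spots_baseline(img, pred_body, cfg)
        assert not (spots & ~pred_body).any()

    def test_empty_body_mask_rejected(self, default_render):
        img, _, _ = default_render
        with pytest.raises(EmptyMaskError):
            extract_spots_baseline(img, np.zeros(img.shape[:2], bool))

    def test_spotless_fish_yields_empty_mask(self):
        from spotid.synthetic import SyntheticFishSpec, render_fish_image
        img, _, _ = render_fish_image(SyntheticFishSpec(n_spots=0, rng_seed=2))
        cfg = BaselineConfig.for_image_size(max(img.shape[:2]))
        body = extract_fish_mask_baseline(img, cfg)
        spots = extract_spots_baseline(img, body, cfg)
        assert spots.sum() < 200  # nothing but stray noise responses


def test_distractors_degrade_baseline_body_mask():
    """Directional check: debris, ruler and off-centre bodies hurt the
    hand-crafted pipeline, which relies on a clean central subject."""
    from spotid.synthetic import SyntheticFishSpec, render_fish_image
    clean, messy = [], []
    for seed in range(6):
        for distractors, centre, sink in (
                ([], None, clean),
                (["ruler_stripe", "debris_blob", "shadow_gradient"],
                 (1040 + 170 * (seed % 3), 420), messy)):
            spec = SyntheticFishSpec(
                rng_seed=seed, distractors=list(distractors),
                body_center=centre)
            img, body, _ = render_fish_image(spec)
            cfg = BaselineConfig.for_image_size(max(img.shape[:2]))
            try:
                pred = extract_fish_mask_baseline(img, cfg)
                sink.append(evaluate_segmentation(pred, body)[2])
            except NoSubjectFoundError:
                sink.append(0.0)
    assert np.mean(messy) < np.mean(clean)
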