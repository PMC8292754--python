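"""RANSAC matcher: invariants, similarity fits, disturbance, mask gate."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from spotid.errors import DegenerateConfigurationError, TooFewSpotsError
from spotid.ransac import (AAConfig, RansacMatcher, SimilarityTransform,
                           build_invariants_aa, estimate_similarity_transform,
                           mask_fscore, pair_error, ransac_match_aa,
                           transform_disturbance)
from spotid.spots import SpotSet
from spotid.synthetic import aligned_body_mask, generate_constellation

from conftest import standard_recapture


def _spotset(xy):
    xy = np.asarray(xy, dtype=float)
    return SpotSet(xy, np.full(len(xy), 1e-4), normalized=True)


class TestInvariants:
    def test_right_triangle_ratios(self):
        s = _spotset([[0, 0], [0.3, 0], [0.3, 0.4]])
        tri = build_invariants_aa(s)
        assert tri.features[0, 0] == pytest.approx(1.25, abs=1e-9)   # L2/L1
        assert tri.features[0, 1] == pytest.approx(4 / 3, abs=1e-9)  # L1/L0

    def test_equilateral_ratios(self):
        s = _spotset([[0, 0], [1, 0], [0.5, math.sqrt(3) / 2]])
        tri = build_invariants_aa(s)
        assert np.allclose(tri.features[0, :2], [1.0, 1.0])

    def test_feature_vector_has_nine_components(self):
        s = _spotset(np.random.default_rng(0).uniform(0, 1, (5, 2)))
        tri = build_invariants_aa(s)
        assert tri.features.shape[1] == 9  # 2 ratios + angle + 6 coords

    def test_coordinates_scaled_down_by_five(self):
        s = _spotset([[0.5, 0.1], [1.0, 0.1], [0.5, 0.6]])
        tri = build_invariants_aa(s)
        coords = tri.features[0, 3:].reshape(3, 2)
        assert np.allclose(sorted(coords[:, 0]),
                           np.array(sorted([0.5, 1.0, 0.5])) / 5)

    def test_too_few_spots(self):
        with pytest.raises(TooFewSpotsError):
            build_invariants_aa(_spotset([[0, 0]]))


class TestSimilarityEstimation:
    def test_identity(self):
        src = np.array([[0, 0], [1, 0], [0, 1]], float)
        t = estimate_similarity_transform(src, src)
        assert t.rotation == pytest.approx(0, abs=1e-12)
        assert t.scale == pytest.approx(1, abs=1e-12)
        assert np.allclose(t.translation, 0)

    def test_exact_recovery(self):
        true = SimilarityTransform(10.0, 1.1, (0.05, -0.02))
        src = np.array([[0.1, 0.2], [0.7, 0.3], [0.4, 0.9]])
        t = estimate_similarity_transform(src, true.apply(src))
        assert t.rotation == pytest.approx(10.0, abs=1e-9)
        assert t.scale == pytest.approx(1.1, abs=1e-9)
        assert np.allclose(t.translation, (0.05, -0.02), atol=1e-9)

    def test_collinear_sources_degenerate(self):
        src = np.array([[0, 0], [0.5, 0.5], [1, 1]])
        with pytest.raises(DegenerateConfigurationError):
            estimate_similarity_transform(src, src + 0.1)


class TestTransformDisturbance:
    @pytest.mark.parametrize("t,expected", [
        (SimilarityTransform(0, 1, (0, 0)), 0.0),
        (SimilarityTransform(60, 1, (0, 0)), 1.0),
        (SimilarityTransform(30, 1.2, (0.1, 0.0)), 0.65),
    ])
    def test_values(self, t, expected):
        assert transform_disturbance(t) == pytest.approx(expected, abs=1e-9)

    @given(st.floats(-50, 50), st.floats(0.5, 2.0),
           st.floats(-0.5, 0.5), st.floats(-0.5, 0.5))
    def test_nonnegative_and_zero_iff_identity(self, rot, scale, tx, ty):
        d = transform_disturbance(SimilarityTransform(rot, scale, (tx, ty)))
        assert d >= 0
        if d == 0:
            assert rot == 0 and scale == 1 and tx == 0 and ty == 0

    def test_monotone_in_each_argument(self):
        base = transform_disturbance(SimilarityTransform(10, 1.1, (0.1, 0.0)))
        assert transform_disturbance(
            SimilarityTransform(20, 1.1, (0.1, 0.0))) > base
        assert transform_disturbance(
            SimilarityTransform(10, 1.3, (0.1, 0.0))) > base
        assert transform_disturbance(
            SimilarityTransform(10, 1.1, (0.2, 0.0))) > base


class TestPairError:
    def test_exact_pair(self):
        t = SimilarityTransform(15, 1.2, (0.1, 0.2))
        src = np.array([0.3, 0.4])
        assert pair_error(t, src, t.apply(src.reshape(1, 2))[0]) == \
            pytest.approx(0, abs=1e-12)

    def test_three_four_five_offset(self):
        t = SimilarityTransform.identity()
        assert pair_error(t, [0, 0], [0.03, 0.04]) == pytest.approx(0.05)


class TestMaskFscore:
    def test_identity_on_identical_masks(self):
        m = aligned_body_mask()
        assert mask_fscore(SimilarityTransform.identity(), m, m) == 1.0

    def test_disjoint_masks(self):
        a = np.zeros((64, 128), bool)
        b = np.zeros((64, 128), bool)
        a[10:20, 10:30] = True
        b[40:50, 80:100] = True
        assert mask_fscore(SimilarityTransform.identity(), a, b) == 0.0

    def test_half_overlap(self):
        a = np.zeros((64, 128), bool)
        b = np.zeros((64, 128), bool)
        a[0:20, 0:40] = True
        b[10:30, 0:40] = True
        f = mask_fscore(SimilarityTransform.identity(), a, b)
        assert f == pytest.approx(0.5, abs=0.01)

    def test_empty_mask_scores_zero(self):
        m = aligned_body_mask()
        assert mask_fscore(SimilarityTransform.identity(),
                           np.zeros_like(m), m) == 0.0


class TestRansacMatch:
    def test_identical_constellations(self, small_individuals):
        ind = small_individuals[0]
        res = ransac_match_aa(ind.spots, ind.mask, ind.spots, ind.mask,
                              seed=1)
        assert res.accepted
        assert res.score == pytest.approx(1.0)
        assert transform_disturbance(res.transform) < 0.01

    def test_transform_recovery_under_perturbation(self, small_individuals):
        from skimage import transform as sktransform

        from spotid.prep import RASTER_PAD_X, RASTER_SCALE, RASTER_SHAPE
        ind = small_individuals[1]
        sp2, truth = standard_recapture(ind.spots, seed=2, rotation=8.0,
                                        scale=1.05)
        # the second photograph's mask moves with the fish: warp it by the
        # true spot transform (fitted on the ground-truth correspondence)
        src = ind.spots.xy[[a for a, _ in truth]]
        dst = sp2.xy[[b for _, b in truth]]
        true_t = estimate_similarity_transform(src, dst)
        s = RASTER_SCALE
        off = np.array([RASTER_PAD_X, RASTER_SHAPE[0] / 2.0])
        to_norm = np.array([[1 / s, 0, -off[0] / s],
                            [0, 1 / s, -off[1] / s], [0, 0, 1]])
        to_raster = np.array([[s, 0, off[0]], [0, s, off[1]], [0, 0, 1]])
        m = to_raster @ true_t.matrix @ to_norm
        mask_b = sktransform.warp(ind.mask.astype(float),
                                  inverse_map=np.linalg.inv(m),
                                  output_shape=ind.mask.shape,
                                  order=0) > 0.5
        res = ransac_match_aa(ind.spots, ind.mask, sp2, mask_b, seed=2)
        assert res.accepted
        assert abs(res.transform.rotation - true_t.rotation) < 1.0
        assert abs(res.transform.scale / true_t.scale - 1) < 0.02
        assert res.mask_fscore >= 0.9

    def test_reproducible_given_seed(self, small_individuals):
        ind = small_individuals[2]
        sp2, _ = standard_recapture(ind.spots, seed=3)
        a = ransac_match_aa(ind.spots, ind.mask, sp2, ind.mask, seed=9)
        b = ransac_match_aa(ind.spots, ind.mask, sp2, ind.mask, seed=9)
        assert a.score == b.score
        assert a.correspondence.pairs == b.correspondence.pairs

    def test_random_negatives_mostly_rejected(self):
        rng = np.random.default_rng(0)
        rejected = 0
        n = 12
        m = RansacMatcher()
        for t in range(n):
            c1 = generate_constellation(
                int(rng.integers(15, 41)), frame=(1.0, 0.4),
                seed=int(rng.integers(2**31)), radius_range=(0.012, 0.02))
            c2 = generate_constellation(
                int(rng.integers(15, 41)), frame=(1.0, 0.4),
                seed=int(rng.integers(2**31)), radius_range=(0.012, 0.02))
            m1 = aligned_body_mask(half_depth=float(rng.uniform(0.13, 0.2)))
            m2 = aligned_body_mask(half_depth=float(rng.uniform(0.13, 0.2)))
            if not m.match(c1, m1, c2, m2, seed=t).accepted:
                rejected += 1
        assert rejected >= 0.75 * n

    def test_coordinate_features_never_worsen_true_match_rank(self):
        # the coordinate features exist to suppress alignments that do
        # not overlay the bodies; they must not push true matches down
        from spotid.pipeline import RansacRanker, rank_matches
        from spotid.studies import build_reidentification_suite
        db, queries, truth = build_reidentification_suite(12, seed=21)

        def ranks(cfg):
            rk = RansacRanker(cfg)
            out = []
            for q in queries:
                r = rank_matches(q, db, rk, seed=3)
                x = r.rank_of(truth[q.record_id])
                out.append(x if x is not None else len(db) + 1)
            return out

        with_coords = ranks(AAConfig(use_coordinate_features=True))
        without = ranks(AAConfig(use_coordinate_features=False))
        assert all(a <= b for a, b in zip(with_coords, without))
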