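"""Triangle-voting matcher: features, matching, voting, verification."""

import math

import numpy as np
import pytest

from spotid.errors import TooFewSpotsError
from spotid.groth import (ALL_FILTERS, GrothConfig, GrothMatcher,
                          TriangleSet, build_triangles_groth, dedupe_spots,
                          groth_match, match_triangles, mutual_nearest,
                          vote_and_assign)
from spotid.spots import SpotSet

from conftest import standard_recapture


def _spotset(xy):
    xy = np.asarray(xy, dtype=float)
    return SpotSet(xy, np.full(len(xy), 1e-4), normalized=True)


class TestDedupe:
    def test_far_points_unchanged(self):
        s = _spotset([[0, 0], [1, 0], [0, 1]])
        out, kept = dedupe_spots(s, epsilon=0.01)
        assert len(out) == 3 and kept.tolist() == [0, 1, 2]

    def test_point_within_two_epsilon_removed(self):
        s = _spotset([[0, 0], [0.002, 0]])
        out, kept = dedupe_spots(s, epsilon=0.001)
        assert kept.tolist() == [0]

    def test_point_at_four_epsilon_kept(self):
        s = _spotset([[0, 0], [0.004, 0]])
        out, _ = dedupe_spots(s, epsilon=0.001)
        assert len(out) == 2


class TestBuildTriangles:
    def test_all_triples_when_knn_covers(self):
        rng = np.random.default_rng(0)
        s = _spotset(rng.uniform(0, 1, (10, 2)))
        tri = build_triangles_groth(s, GrothConfig(knn=25))
        assert len(tri) == math.comb(10, 3)

    def test_right_triangle_features(self):
        # sides 3-4-5 scaled into the unit frame
        s = _spotset([[0, 0], [0.3, 0], [0.3, 0.4]])
        tri = build_triangles_groth(s)[0]
        assert tri.ratio == pytest.approx(5 / 3, abs=1e-9)
        assert tri.cosine == pytest.approx(0.6, abs=1e-9)
        assert tri.log_perimeter == pytest.approx(math.log(1.2), abs=1e-9)

    def test_equilateral_features(self):
        s = _spotset([[0, 0], [1, 0], [0.5, math.sqrt(3) / 2]])
        tri = build_triangles_groth(s)[0]
        assert tri.ratio == pytest.approx(1.0, abs=1e-9)
        assert tri.cosine == pytest.approx(0.5, abs=1e-9)

    def test_too_few_spots(self):
        with pytest.raises(TooFewSpotsError):
            build_triangles_groth(_spotset([[0, 0], [1, 1]]))

    def test_tolerances_positive(self):
        rng = np.random.default_rng(1)
        tri = build_triangles_groth(_spotset(rng.uniform(0, 1, (8, 2))))
        assert (tri.tol_r2 > 0).all() and (tri.tol_c2 >= 0).all()


class TestMutualNearest:
    def test_equals_brute_force(self):
        rng = np.random.default_rng(5)
        a = build_triangles_groth(_spotset(rng.uniform(0, 1, (9, 2))))
        b = build_triangles_groth(_spotset(rng.uniform(0, 1, (9, 2))))
        ia, ib, _ = mutual_nearest(a, b)
        # brute force all-pairs mutual nearest neighbours
        d = np.linalg.norm(a.features[:, None] - b.features[None], axis=2)
        nb = d.argmin(axis=1)
        na = d.argmin(axis=0)
        expected = {(i, nb[i]) for i in range(len(a)) if na[nb[i]] == i}
        assert set(zip(ia.tolist(), ib.tolist())) == expected

    def test_identical_sets_pair_with_themselves(self):
        rng = np.random.default_rng(2)
        s = _spotset(rng.uniform(0, 1, (12, 2)))
        tri = build_triangles_groth(s)
        tri2 = build_triangles_groth(s.copy())
        ia, ib, d = mutual_nearest(tri, tri2)
        assert (ia == ib).all() and len(ia) == len(tri)
        assert np.allclose(d, 0)


class TestMatchTriangles:
    def test_mirroring_flips_handedness_and_blocks_counterparts(self):
        rng = np.random.default_rng(3)
        xy = rng.uniform(0, 1, (12, 2))
        s = _spotset(xy)
        flipped = _spotset(np.column_stack([1 - xy[:, 0], xy[:, 1]]))
        ta = build_triangles_groth(s)
        tb = build_triangles_groth(flipped)
        # every triangle's mirrored counterpart has opposite orientation
        by_triple = {tuple(sorted(v)): i for i, v in enumerate(tb.ordered)}
        for i, v in enumerate(ta.ordered):
            j = by_triple[tuple(sorted(v))]
            assert ta.handed[i] == -tb.handed[j]
        # hence the handedness filter never pairs a triangle with its
        # own mirror image
        ia, ib, _ = match_triangles(ta, tb, GrothConfig(),
                                    filters=("handedness",))
        for i, j in zip(ia, ib):
            assert by_triple[tuple(sorted(ta.ordered[i]))] != j

    def test_filters_only_remove_candidates(self):
        # monotone pruning: dropping a filter never loses matched triangles
        rng = np.random.default_rng(4)
        a = _spotset(rng.uniform(0, 1, (15, 2)))
        b, _ = standard_recapture(a, seed=1)
        ta, tb = build_triangles_groth(a), build_triangles_groth(b)
        cfg = GrothConfig(consistency_recentring=False)
        full = match_triangles(ta, tb, cfg, filters=ALL_FILTERS)
        for k in range(len(ALL_FILTERS)):
            subset = ALL_FILTERS[:k]
            fewer = match_triangles(ta, tb, cfg, filters=subset)
            assert set(full[0].tolist()) <= set(fewer[0].tolist())


class TestVoteAndAssign:
    @staticmethod
    def _single_triangle_sets():
        a = build_triangles_groth(_spotset([[0, 0], [0.3, 0], [0.3, 0.4]]))
        b = build_triangles_groth(_spotset([[0, 0], [0.3, 0], [0.3, 0.4]]))
        return a, b

    def test_single_matched_triangle_assigns_three_pairs(self):
        a, b = self._single_triangle_sets()
        matches = (np.array([0]), np.array([0]), np.array([0.0]))
        corr, diag = vote_and_assign(a, b, matches)
        assert len(corr) == 3
        assert all(x == y for x, y in corr)
        assert diag["total_votes"] == 3

    def test_reuse_stops_assignment_under_strict_policy(self):
        # hand-built vote table: the second-ranked pair reuses point 0
        ordered_a = np.array([[0, 1, 2], [0, 1, 3]])
        ordered_b = np.array([[0, 1, 2], [5, 1, 3]])
        tri_a = TriangleSet(ordered_a, np.ones(2), np.full(2, 0.5),
                            np.zeros(2), np.ones(2, int), np.zeros(2),
                            np.full(2, 1e-4), np.full(2, 1e-4))
        tri_b = TriangleSet(ordered_b, np.ones(2), np.full(2, 0.5),
                            np.zeros(2), np.ones(2, int), np.zeros(2),
                            np.full(2, 1e-4), np.full(2, 1e-4))
        matches = (np.array([0, 0, 1]), np.array([0, 0, 1]),
                   np.array([0.0, 0.0, 0.1]))
        cfg = GrothConfig(reuse_policy="stop", drop_baseline="first")
        corr, _ = vote_and_assign(tri_a, tri_b, matches, cfg)
        # pairs (0,0),(1,1),(2,2) earn 2 votes each; the triangle pair
        # (1,1) then votes (0,5) which would reuse point 0 -> stop
        assert (0, 5) not in corr.pairs
        assert set(corr.pairs) <= {(0, 0), (1, 1), (2, 2), (3, 3)}

    def test_skip_policy_passes_over_conflicts(self):
        tri_a, tri_b = self._single_triangle_sets()
        matches = (np.array([0, 0]), np.array([0, 0]),
                   np.array([0.0, 0.0]))
        corr, _ = vote_and_assign(tri_a, tri_b, matches,
                                  GrothConfig(reuse_policy="skip"))
        assert len(corr) == 3


class TestGrothMatch:
    def test_self_match_recovers_everything(self, small_individuals):
        ind = small_individuals[0]
        res = groth_match(ind.spots, ind.spots)
        assert res.accepted
        assert len(res.correspondence) == len(ind.spots)
        assert res.score == pytest.approx(len(ind.spots), rel=0.05)

    def test_too_few_spots_is_rejected_not_raised(self):
        res = groth_match(_spotset([[0, 0], [1, 1]]),
                          _spotset([[0, 0], [1, 1]]))
        assert not res.accepted and res.score is None

    def test_two_round_verification_rejects_unstable_match(self):
        # under the strict two-round rule, a noisy match whose second
        # round reproduces fewer pairs is declared impossible to match
        from spotid.studies import make_individual
        cfg = GrothConfig(verification="two_round")
        m = GrothMatcher(cfg)
        saw_dropout = False
        for seed in range(12):
            ind = make_individual(seed + 1)
            sp2, _ = standard_recapture(ind.spots, seed=seed)
            res = m.match(ind.spots, sp2)
            if res.diagnostics.get("reason") == "verification dropout":
                saw_dropout = True
                assert res.score == 0.0
                assert len(res.correspondence) == 0
        assert saw_dropout

    def test_recovery_on_standard_recaptures(self, small_individuals):
        # the op-level contract: most surviving true pairs are recovered
        recovs = []
        for i, ind in enumerate(small_individuals):
            sp2, corr = standard_recapture(ind.spots, seed=i)
            res = groth_match(ind.spots, sp2)
            got = set(res.correspondence.pairs)
            recovs.append(len(got & set(corr.pairs)) / len(corr))
        assert np.mean(recovs) >= 0.8

    def test_symmetry_of_decisions(self, small_individuals):
        a, b = small_individuals[0], small_individuals[1]
        sp2, _ = standard_recapture(a.spots, seed=5)
        for x, y in [(a.spots, sp2), (a.spots, b.spots)]:
            fwd = groth_match(x, y)
            rev = groth_match(y, x)
            assert fwd.accepted == rev.accepted

    def test_self_score_beats_perturbed_nonmatch(self, small_individuals):
        a, b = small_individuals[2], small_individuals[3]
        self_score = groth_match(a.spots, a.spots).score
        cross = groth_match(a.spots, b.spots).score or 0.0
        assert self_score > cross
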