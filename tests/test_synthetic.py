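"""Generator tests: constellations, perturbations, renders, populations."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from spotid.histories import CaptureRecord
from spotid.synthetic import (PerturbationSpec, PopulationSimSpec,
                              SyntheticFishSpec, generate_constellation,
                              inject_tag_loss, observed_history_matrix,
                              perturb_constellation, render_fish_image,
                              simulate_capture_histories)


class TestGenerateConstellation:
    def test_empty(self):
        assert len(generate_constellation(0, seed=1)) == 0

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError):
            generate_constellation(-1)

    def test_bounds_and_count(self):
        s = generate_constellation(30, frame=(1000, 400), seed=1)
        assert len(s) == 30
        assert (s.xy >= 0).all()
        assert (s.xy[:, 0] <= 1000).all() and (s.xy[:, 1] <= 400).all()

    def test_deterministic(self):
        a = generate_constellation(20, seed=7)
        b = generate_constellation(20, seed=7)
        assert a.allclose(b)

    def test_minimum_separation_is_twice_max_radius(self):
        rr = (0.01, 0.016)
        s = generate_constellation(40, frame=(1.0, 0.4), seed=3,
                                   radius_range=rr)
        d = np.linalg.norm(s.xy[:, None] - s.xy[None], axis=2)
        np.fill_diagonal(d, np.inf)
        assert d.min() >= 2 * rr[1] - 1e-12


class TestPerturbConstellation:
    def test_identity_is_identity(self):
        s = generate_constellation(15, seed=2)
        out, corr = perturb_constellation(s, PerturbationSpec(rng_seed=0))
        assert out.allclose(s)
        assert corr.pairs == [(i, i) for i in range(15)]

    def test_floor_drop_rule(self):
        s = generate_constellation(30, seed=2)
        out, corr = perturb_constellation(
            s, PerturbationSpec(drop_fraction=0.5, rng_seed=1))
        assert len(corr) == 15
        assert len(out) == 15

    def test_rotation_matches_direct_transform(self):
        # oracle: apply the rotation about the centroid by hand
        s = generate_constellation(12, seed=5)
        out, corr = perturb_constellation(
            s, PerturbationSpec(rotation=10.0, rng_seed=0))
        th = np.radians(10.0)
        rot = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        c = s.xy.mean(axis=0)
        expected = (s.xy - c) @ rot.T + c
        for a, b in corr:
            assert np.allclose(out.xy[b], expected[a], atol=1e-9)

    def test_conservation_of_counts(self):
        s = generate_constellation(24, seed=9)
        spec = PerturbationSpec(drop_fraction=0.25, add_count=5, rng_seed=4)
        out, corr = perturb_constellation(s, spec)
        n_drop = int(np.floor(24 * 0.25))
        assert len(corr) == 24 - n_drop
        assert len(out) == 24 - n_drop + 5

    def test_added_spots_keep_separation(self):
        s = generate_constellation(20, seed=3, radius_range=(0.012, 0.02))
        out, _ = perturb_constellation(
            s, PerturbationSpec(add_count=4, rng_seed=8))
        d = np.linalg.norm(out.xy[:, None] - out.xy[None], axis=2)
        np.fill_diagonal(d, np.inf)
        min_sep = 2 * np.sqrt(s.sizes.max() / np.pi)
        assert d[20:, :].min() >= min_sep - 1e-9

    def test_invalid_drop_fraction(self):
        with pytest.raises(ValueError):
            PerturbationSpec(drop_fraction=1.5)

    def test_empty_input_rejected(self):
        from spotid.spots import SpotSet
        with pytest.raises(ValueError):
            perturb_constellation(SpotSet.empty(), PerturbationSpec())


class TestRenderFishImage:
    def test_spot_mask_subset_of_body(self, default_render):
        _, body, spots = default_render
        assert not (spots & ~body).any()

    def test_no_spots(self):
        spec = SyntheticFishSpec(n_spots=0, frame=(600, 300),
                                 body_axes=(200, 60),
                                 spot_radius_range=(5, 8), rng_seed=1)
        _, _, spots = render_fish_image(spec)
        assert not spots.any()

    def test_bit_identical_given_seed(self):
        spec = SyntheticFishSpec(frame=(600, 300), body_axes=(200, 60),
                                 spot_radius_range=(5, 8), n_spots=8,
                                 rng_seed=5)
        a = render_fish_image(spec)
        b = render_fish_image(spec)
        assert (a[0] == b[0]).all() and (a[1] == b[1]).all() \
            and (a[2] == b[2]).all()

    def test_oversized_spot_radius_rejected(self):
        with pytest.raises(ValueError):
            SyntheticFishSpec(body_axes=(200, 30), spot_radius_range=(10, 40))

    def test_level_ordering_enforced(self):
        with pytest.raises(ValueError):
            SyntheticFishSpec(background_level=50, body_level=80)

    def test_spot_pattern_is_pose_invariant(self):
        # same individual rendered in two poses carries the same spots
        base = dict(frame=(800, 500), body_axes=(260, 80), n_spots=10,
                    spot_radius_range=(6, 9), rng_seed=3)
        _, _, s0 = render_fish_image(SyntheticFishSpec(**base))
        _, _, s1 = render_fish_image(
            SyntheticFishSpec(body_rotation=20.0, **base))
        # pixel counts agree to within raster effects
        assert abs(int(s0.sum()) - int(s1.sum())) < 0.1 * s0.sum()


class TestCaptureHistories:
    def test_degenerate_always_alive_always_caught(self):
        m = simulate_capture_histories(PopulationSimSpec(
            n_individuals=50, n_occasions=5, phi=1.0, p=1.0, rng_seed=0))
        assert (m.y == 1).all()

    def test_no_survival_means_no_recaptures(self):
        m = simulate_capture_histories(PopulationSimSpec(
            n_individuals=200, n_occasions=6, phi=0.0, p=0.6, rng_seed=1))
        assert (m.y.sum(axis=1) == 1).all()

    def test_next_occasion_recapture_rate_matches_phi_p(self):
        # closed form: P(seen at t+1 | first caught at t) = phi * p
        spec = PopulationSimSpec(n_individuals=10000, n_occasions=5,
                                 phi=0.5, p=0.5, rng_seed=11)
        m = simulate_capture_histories(spec)
        f = m.first_capture
        ok = f < m.n_occasions - 1
        seen_next = m.y[np.arange(m.n), np.minimum(f + 1,
                                                   m.n_occasions - 1)]
        frac = seen_next[ok].mean()
        n = ok.sum()
        se = np.sqrt(0.25 * 0.75 / n)
        assert abs(frac - 0.25) < 3 * se

    def test_three_occasion_history_frequencies_match_enumeration(self):
        # oracle: exhaustive enumeration over alive/dead paths gives
        # P(no recapture after first capture at t=0) = 0.6875 at phi=p=0.5
        spec = PopulationSimSpec(n_individuals=10000, n_occasions=3,
                                 phi=0.5, p=0.5, rng_seed=21)
        m = simulate_capture_histories(spec)
        first0 = m.y[:, 0] == 1
        rows = m.y[first0]
        p100 = ((rows[:, 1] == 0) & (rows[:, 2] == 0)).mean()
        se = np.sqrt(0.6875 * (1 - 0.6875) / len(rows))
        assert abs(p100 - 0.6875) < 3 * se


class TestInjectTagLoss:
    @staticmethod
    def _records(n=200, reps=6):
        return [CaptureRecord(f"f{i:03d}", t, f"f{i:03d}")
                for i in range(n) for t in range(reps)]

    def test_zero_rate_unchanged(self):
        recs = self._records(20, 4)
        assert inject_tag_loss(recs, 0.0, seed=1) == sorted(
            recs, key=lambda r: (r.occasion, r.true_id))

    def test_rate_one_fragments_every_recapture(self):
        out = inject_tag_loss(self._records(10, 4), 1.0, seed=1)
        mat = observed_history_matrix(out, 4)
        assert (mat.y.sum(axis=1) == 1).all()

    def test_binomial_fragment_count(self):
        # 200 individuals x 5 recaptures = 1000 recapture events at 7%
        recs = self._records(200, 6)
        out = inject_tag_loss(recs, 0.07, seed=5)
        fresh = {r.observed_id for r in out if r.observed_id.startswith("lost")}
        se = np.sqrt(1000 * 0.07 * 0.93)
        assert abs(len(fresh) - 70) < 3 * se

    def test_invalid_rate(self):
        with pytest.raises(ValueError):
            inject_tag_loss([], 1.2)


@given(st.integers(min_value=1, max_value=30), st.integers(0, 2**31 - 1))
def test_constellation_sizes_positive(n, seed):
    s = generate_constellation(n, seed=seed % 1000)
    assert (s.sizes > 0).all()
    assert len(s) == n
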