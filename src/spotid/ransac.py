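"""RANSAC constellation matcher with similarity transforms and mask gating.

Triangles are described by the side-length ratios L2/L1 and L1/L0 (with
L2 >= L1 >= L0), the angle from the triangle centroid to the vertex where
the two shortest sides meet, and the vertex coordinates scaled down by a
factor of 5 so their magnitude matches the other features.  Matched
triangle pairs (mutual nearest neighbours in this feature space) seed a
RANSAC loop: each candidate triangle pair yields a similarity transform
(rotation + uniform scale + translation), scored by the fraction of
matched triangles whose worst vertex reprojection error is below a
threshold.  A transformation-disturbance penalty (rotation/60 +
|scale-1|/2 + Manhattan translation/2) discourages implausibly large
alignments between body-aligned constellations, and a Dice overlap gate
on the transformed body masks rejects alignments that do not put the two
bodies on top of each other.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree
from skimage import transform as sktransform

from .errors import DegenerateConfigurationError, TooFewSpotsError
from .prep import RASTER_PAD_X, RASTER_SCALE, RASTER_SHAPE
from .results import MatchResult
from .spots import Correspondence, SpotSet

__all__ = [
    "AAConfig",
    "SimilarityTransform",
    "AATriangleSet",
    "build_invariants_aa",
    "estimate_similarity_transform",
    "transform_disturbance",
    "pair_error",
    "mask_fscore",
    "ransac_match_aa",
    "RansacMatcher",
]


@dataclass
class AAConfig:
    knn: int = 15                       # neighbours used to form triangles
    inlier_error_threshold: float = 0.01  # fish-length units
    consensus_fraction: float = 0.85    # triangle-inlier fraction to accept
    max_disturbance: float = 1.0        # transformation-disturbance cap
    max_iterations: int = 500           # RANSAC candidate budget
    mask_fscore_min: float = 0.75       # Dice gate on transformed masks
    coord_scale: float = 5.0            # vertex-coordinate down-scaling
    use_coordinate_features: bool = True

    def __post_init__(self):
        if not 0 < self.consensus_fraction <= 1:
            raise ValueError("consensus_fraction must lie in (0, 1]")
        if min(self.inlier_error_threshold, self.max_disturbance,
               self.max_iterations, self.mask_fscore_min,
               self.coord_scale) <= 0:
            raise ValueError("all thresholds must be positive")


@dataclass
class SimilarityTransform:
    """Rotation (degrees, CCW) + uniform scale + translation."""

    rotation: float
    scale: float
    translation: tuple[float, float]

    def __post_init__(self):
        if self.scale <= 0:
            raise ValueError("scale must be positive")

    @property
    def matrix(self) -> np.ndarray:
        th = math.radians(self.rotation)
        a = self.scale * math.cos(th)
        b = self.scale * math.sin(th)
        tx, ty = self.translation
        return np.array([[a, -b, tx], [b, a, ty], [0.0, 0.0, 1.0]])

    def apply(self, points: np.ndarray) -> np.ndarray:
        points = np.asarray(points, dtype=float)
        m = self.matrix
        return points @ m[:2, :2].T + m[:2, 2]

    @classmethod
    def identity(cls) -> "SimilarityTransform":
        return cls(0.0, 1.0, (0.0, 0.0))


class AATriangleSet:
    """Vectorized triangle table with ratio/angle/coordinate features."""

    def __init__(self, ordered: np.ndarray, xy: np.ndarray,
                 features: np.ndarray):
        self.ordered = ordered          # (m, 3): vertices (L0^L1, L0^L2, L1^L2)
        self.xy = xy
        self.features = features
        self._tree = None

    def __len__(self) -> int:
        return len(self.ordered)

    @property
    def tree(self) -> cKDTree:
        if self._tree is None:
            self._tree = cKDTree(self.features)
        return self._tree

    def vertex_points(self) -> np.ndarray:
        """Ordered vertex coordinates, shape (m, 3, 2)."""
        return self.xy[self.ordered]


def build_invariants_aa(spots: SpotSet, cfg: AAConfig | None = None
                        ) -> AATriangleSet:
    """Build the triangle invariant table for one constellation."""
    cfg = cfg or AAConfig()
    if len(spots) < 3:
        raise TooFewSpotsError(f"need >= 3 spots, have {len(spots)}")
    from .groth import _neighbour_triplets
    tri = _neighbour_triplets(spots.xy, cfg.knn)
    p = spots.xy[tri]                               # (m, 3, 2)
    side_vec = p[:, [1, 2, 0], :] - p               # side k joins k, k+1
    side_len = np.hypot(side_vec[..., 0], side_vec[..., 1])
    order = np.argsort(side_len, axis=1, kind="stable")
    rows = np.arange(len(tri))
    l0 = side_len[rows, order[:, 0]]
    l1 = side_len[rows, order[:, 1]]
    l2 = side_len[rows, order[:, 2]]
    # vertex opposite side k is (k + 2) % 3
    v0 = tri[rows, (order[:, 2] + 2) % 3]           # L0 ^ L1 (opposite L2)
    v1 = tri[rows, (order[:, 1] + 2) % 3]           # L0 ^ L2
    v2 = tri[rows, (order[:, 0] + 2) % 3]           # L1 ^ L2
    with np.errstate(divide="ignore", invalid="ignore"):
        r21 = l2 / l1
        r10 = l1 / l0
    centroid = p.mean(axis=1)
    rel = spots.xy[v0] - centroid
    angle = np.arctan2(rel[:, 1], rel[:, 0])
    cols = [r21, r10, angle]
    ordered = np.column_stack([v0, v1, v2])
    if cfg.use_coordinate_features:
        coords = spots.xy[ordered].reshape(len(tri), 6) / cfg.coord_scale
        features = np.column_stack(cols + [coords])
    else:
        features = np.column_stack(cols)
    return AATriangleSet(ordered, spots.xy, features)


def _fit_similarity(src: np.ndarray, dst: np.ndarray
                    ) -> tuple[float, float, float, float]:
    """Least-squares similarity fit; returns (a, b, tx, ty).

    The transform is x' = a x - b y + tx, y' = b x + a y + ty.
    """
    src = np.asarray(src, dtype=float)
    dst = np.asarray(dst, dtype=float)
    sm = src.mean(axis=0)
    dm = dst.mean(axis=0)
    sc = src - sm
    dc = dst - dm
    denom = np.einsum("ij,ij->", sc, sc)
    if denom <= 0:
        raise DegenerateConfigurationError("coincident source points")
    a = np.einsum("ij,ij->", sc, dc) / denom
    b = (sc[:, 0] @ dc[:, 1] - sc[:, 1] @ dc[:, 0]) / denom
    tx, ty = dm - np.array([a * sm[0] - b * sm[1],
                            b * sm[0] + a * sm[1]])
    return float(a), float(b), float(tx), float(ty)


def _params_to_transform(a, b, tx, ty) -> SimilarityTransform:
    scale = math.hypot(a, b)
    if scale <= 0:
        raise DegenerateConfigurationError("zero-scale transform")
    return SimilarityTransform(rotation=math.degrees(math.atan2(b, a)),
                               scale=scale, translation=(tx, ty))


def estimate_similarity_transform(src: np.ndarray, dst: np.ndarray
                                  ) -> SimilarityTransform:
    """Least-squares rotation + uniform scale + translation, src -> dst.

    Exact when the correspondences are truly related by such a transform.
    Raises :class:`DegenerateConfigurationError` for collinear or
    coincident source points (with exactly three pairs the fit would be
    unstable in the normal direction).
    """
    src = np.asarray(src, dtype=float)
    dst = np.asarray(dst, dtype=float)
    if src.shape != dst.shape or src.shape[0] < 2:
        raise ValueError("need >= 2 matching point pairs of equal shape")
    if src.shape[0] == 3:
        v1 = src[1] - src[0]
        v2 = src[2] - src[0]
        area2 = abs(v1[0] * v2[1] - v1[1] * v2[0])
        span = max(np.hypot(*v1), np.hypot(*v2))
        if span == 0 or area2 < 1e-12 * span**2:
            raise DegenerateConfigurationError(
                "collinear or coincident source points")
    return _params_to_transform(*_fit_similarity(src, dst))


def transform_disturbance(t: SimilarityTransform) -> float:
    """Penalty rotation/60 + |scale - 1|/2 + Manhattan displacement/2.

    Rotation enters in absolute degrees; translation in normalized units.
    Zero iff the transform is the identity.
    """
    manhattan = abs(t.translation[0]) + abs(t.translation[1])
    return abs(t.rotation) / 60.0 + abs(t.scale - 1.0) / 2.0 + manhattan / 2.0


def pair_error(t: SimilarityTransform, source, target) -> float:
    """Reprojection error ||t(source) - target|| of one point pair.

    For a similarity point transform the first-order (Sampson-style)
    geometric error reduces to the Euclidean reprojection distance.
    """
    src = np.asarray(source, dtype=float)
    tgt = np.asarray(target, dtype=float)
    diff = t.apply(src.reshape(-1, 2)) - tgt.reshape(-1, 2)
    err = np.hypot(diff[:, 0], diff[:, 1])
    return float(err[0]) if err.size == 1 else err


def transform_canonical_mask(mask: np.ndarray,
                             t: SimilarityTransform) -> np.ndarray:
    """Warp a canonical-raster mask by a normalized-unit similarity."""
    mask = np.asarray(mask, dtype=bool)
    s = RASTER_SCALE
    off = np.array([RASTER_PAD_X, RASTER_SHAPE[0] / 2.0])
    to_norm = np.array([[1 / s, 0, -off[0] / s],
                        [0, 1 / s, -off[1] / s],
                        [0, 0, 1]])
    to_raster = np.array([[s, 0, off[0]], [0, s, off[1]], [0, 0, 1]])
    m = to_raster @ t.matrix @ to_norm
    warped = sktransform.warp(mask.astype(float),
                              inverse_map=np.linalg.inv(m),
                              output_shape=mask.shape, order=0)
    return warped > 0.5


def mask_fscore(t: SimilarityTransform, mask_a: np.ndarray,
                mask_b: np.ndarray) -> float:
    """Dice overlap of ``mask_a`` transformed by ``t`` against ``mask_b``.

    Both masks live in the canonical aligned raster; the transform is in
    normalized fish-length units and is conjugated into raster pixels.
    """
    mask_a = np.asarray(mask_a, dtype=bool)
    mask_b = np.asarray(mask_b, dtype=bool)
    if not mask_a.any() or not mask_b.any():
        return 0.0
    s = RASTER_SCALE
    off = np.array([RASTER_PAD_X, RASTER_SHAPE[0] / 2.0])
    to_norm = np.array([[1 / s, 0, -off[0] / s],
                        [0, 1 / s, -off[1] / s],
                        [0, 0, 1]])
    to_raster = np.array([[s, 0, off[0]], [0, s, off[1]], [0, 0, 1]])
    m = to_raster @ t.matrix @ to_norm
    warped = sktransform.warp(mask_a.astype(float),
                              inverse_map=np.linalg.inv(m),
                              output_shape=mask_a.shape, order=0)
    a_t = warped > 0.5
    inter = np.count_nonzero(a_t & mask_b)
    return 2.0 * inter / (a_t.sum() + mask_b.sum())


class RansacMatcher:
    """Reusable RANSAC matcher with per-constellation preparation caching."""

    _CHUNK = 64
    _SCREEN = 384   # matched-triangle subsample for candidate screening

    def __init__(self, cfg: AAConfig | None = None):
        self.cfg = cfg or AAConfig()

    def prepare(self, spots: SpotSet):
        if len(spots) < 3:
            return None
        return build_invariants_aa(spots, self.cfg)

    def match_prepared(self, tri_a, tri_b, spots_a: SpotSet,
                       spots_b: SpotSet, mask_a, mask_b,
                       seed: int = 0) -> MatchResult:
        cfg = self.cfg
        if tri_a is None or tri_b is None:
            return MatchResult(Correspondence([]), None, False,
                               diagnostics={"reason": "too few spots"})
        d_ab, nn_b = tri_b.tree.query(tri_a.features)
        _, nn_a = tri_a.tree.query(tri_b.features)
        a_idx = np.arange(len(tri_a))
        mutual = nn_a[nn_b] == a_idx
        ia, ib = a_idx[mutual], nn_b[mutual]
        if len(ia) == 0:
            return MatchResult(Correspondence([]), None, False,
                               diagnostics={"reason": "no matched triangles"})

        pts_a = tri_a.vertex_points()[ia]          # (m, 3, 2)
        pts_b = tri_b.vertex_points()[ib]
        m = len(ia)
        rng = np.random.default_rng(seed)
        order = rng.permutation(m)[:cfg.max_iterations]

        # candidate screening evaluates errors on a fixed subsample of the
        # matched triangles (plenty for an inlier-fraction estimate); the
        # selected candidate's full inlier set is computed afterwards
        if m > self._SCREEN:
            screen = np.sort(rng.choice(m, size=self._SCREEN, replace=False))
        else:
            screen = np.arange(m)
        sa_x = pts_a[screen, :, 0].astype(np.float32)[None]   # (1, s, 3)
        sa_y = pts_a[screen, :, 1].astype(np.float32)[None]
        sb_x = pts_b[screen, :, 0].astype(np.float32)[None]
        sb_y = pts_b[screen, :, 1].astype(np.float32)[None]

        thresh = cfg.inlier_error_threshold
        best_fallback = None          # >=85% but beyond the disturbance cap
        best_overall = None           # classical best-consensus candidate
        chosen_params = None
        n_cand = 0
        early = False
        for start in range(0, len(order), self._CHUNK):
            chunk = order[start:start + self._CHUNK]
            params = self._fit_batch(pts_a[chunk], pts_b[chunk])
            if params is None:
                continue
            a, b, tx, ty, bad = params
            a32 = a.astype(np.float32)[:, None, None]
            b32 = b.astype(np.float32)[:, None, None]
            ex = (a32 * sa_x - b32 * sa_y
                  + tx.astype(np.float32)[:, None, None] - sb_x)
            ey = (b32 * sa_x + a32 * sa_y
                  + ty.astype(np.float32)[:, None, None] - sb_y)
            tri_err = np.hypot(ex, ey).max(axis=2)  # (chunk, s)
            frac = (tri_err <= thresh).mean(axis=1)
            n_cand += len(chunk)
            scale = np.hypot(a, b)
            rot = np.degrees(np.arctan2(b, a))
            dist = (np.abs(rot) / 60.0 + np.abs(scale - 1.0) / 2.0
                    + (np.abs(tx) + np.abs(ty)) / 2.0)
            ok = ~bad
            cons = ok & (frac >= cfg.consensus_fraction)
            early_ok = cons & (dist <= cfg.max_disturbance)
            if early_ok.any():
                # consensus reached with a plausible transform: stop early
                k = int(np.argmax(early_ok))
                chosen_params = (a[k], b[k], tx[k], ty[k])
                early = True
                break
            for k in np.nonzero(cons)[0]:
                if best_fallback is None or dist[k] < best_fallback[0]:
                    best_fallback = (dist[k], (a[k], b[k], tx[k], ty[k]))
            plaus = ok & ~cons & (dist <= cfg.max_disturbance)
            if plaus.any():
                keys = np.where(plaus, frac, -1.0)
                k = int(np.argmax(keys))  # ties: first in candidate order
                key = (frac[k], -dist[k])
                if best_overall is None or key > best_overall[0]:
                    best_overall = (key, (a[k], b[k], tx[k], ty[k]))
        if chosen_params is None and best_fallback is not None:
            chosen_params = best_fallback[1]
        if chosen_params is None and best_overall is not None:
            chosen_params = best_overall[1]
        chosen = None
        if chosen_params is not None:
            ca, cb, ctx, cty = chosen_params
            px = ca * pts_a[..., 0] - cb * pts_a[..., 1] + ctx - pts_b[..., 0]
            py = cb * pts_a[..., 0] + ca * pts_a[..., 1] + cty - pts_b[..., 1]
            chosen = np.hypot(px, py).max(axis=1) <= thresh
        if chosen is None or not chosen.any():
            return MatchResult(Correspondence([]), None, False,
                               diagnostics={"reason": "no consensus",
                                            "candidates": n_cand,
                                            "matched_triangles": m})

        # refit on all vertex pairs of the inlier triangles, then refine
        # once more on the point pairs the refit itself deems inliers
        seed_idx = np.column_stack([
            tri_a.ordered[ia[chosen]].reshape(-1),
            tri_b.ordered[ib[chosen]].reshape(-1)])
        seed_idx = np.unique(seed_idx, axis=0)
        final = _params_to_transform(*_fit_similarity(
            spots_a.xy[seed_idx[:, 0]], spots_b.xy[seed_idx[:, 1]]))
        # refine against the vertex pairs of *all* matched triangles: the
        # pairs the current fit deems inliers are refit, twice
        pair_idx = np.unique(np.column_stack([
            tri_a.ordered[ia].reshape(-1),
            tri_b.ordered[ib].reshape(-1)]), axis=0)
        for _ in range(2):
            errs = np.atleast_1d(pair_error(
                final, spots_a.xy[pair_idx[:, 0]],
                spots_b.xy[pair_idx[:, 1]]))
            good = errs <= thresh
            if good.sum() < 2 or good.all():
                break
            final = _params_to_transform(*_fit_similarity(
                spots_a.xy[pair_idx[good, 0]],
                spots_b.xy[pair_idx[good, 1]]))

        errs = pair_error(final, spots_a.xy[pair_idx[:, 0]],
                          spots_b.xy[pair_idx[:, 1]])
        errs = np.atleast_1d(errs)
        ok = errs <= thresh
        inlier_pairs = pair_idx[ok]
        src_in = np.unique(inlier_pairs[:, 0])
        tgt_in = np.unique(inlier_pairs[:, 1])
        score = (len(tgt_in) / len(spots_b)) * (len(src_in) / len(spots_a))

        # injective correspondence: best error first
        corr = []
        used_a, used_b = set(), set()
        for k in np.argsort(errs[ok], kind="stable"):
            pa, pb = int(inlier_pairs[k, 0]), int(inlier_pairs[k, 1])
            if pa in used_a or pb in used_b:
                continue
            corr.append((pa, pb))
            used_a.add(pa)
            used_b.add(pb)

        fscore = mask_fscore(final, mask_a, mask_b)
        if fscore < cfg.mask_fscore_min:
            return MatchResult(Correspondence(corr), None, False,
                               transform=final, mask_fscore=fscore,
                               diagnostics={"reason": "mask gate",
                                            "raw_score": float(score),
                                            "candidates": n_cand})
        return MatchResult(Correspondence(corr), float(score), True,
                           transform=final, mask_fscore=fscore,
                           diagnostics={"candidates": n_cand,
                                        "early_consensus": early,
                                        "matched_triangles": m})

    @staticmethod
    def _fit_batch(src: np.ndarray, dst: np.ndarray):
        """Vectorized 3-point similarity fits; returns None if all degenerate."""
        sm = src.mean(axis=1, keepdims=True)
        dm = dst.mean(axis=1, keepdims=True)
        sc = src - sm
        dc = dst - dm
        denom = np.einsum("mij,mij->m", sc, sc)
        with np.errstate(divide="ignore", invalid="ignore"):
            a = np.einsum("mij,mij->m", sc, dc) / denom
            b = (np.einsum("mi,mi->m", sc[..., 0], dc[..., 1])
                 - np.einsum("mi,mi->m", sc[..., 1], dc[..., 0])) / denom
        bad = ~np.isfinite(a) | ~np.isfinite(b) | (np.hypot(a, b) <= 0)
        a[bad] = 1.0
        b[bad] = 0.0
        tx = dm[:, 0, 0] - (a * sm[:, 0, 0] - b * sm[:, 0, 1])
        ty = dm[:, 0, 1] - (b * sm[:, 0, 0] + a * sm[:, 0, 1])
        if bad.all():
            return None
        return a, b, tx, ty, bad

    def match(self, spots_a: SpotSet, mask_a, spots_b: SpotSet,
              mask_b, seed: int = 0) -> MatchResult:
        return self.match_prepared(self.prepare(spots_a),
                                   self.prepare(spots_b),
                                   spots_a, spots_b, mask_a, mask_b,
                                   seed=seed)


def ransac_match_aa(spots_a: SpotSet, mask_a, spots_b: SpotSet, mask_b,
                    cfg: AAConfig | None = None,
                    seed: int = 0) -> MatchResult:
    """Match two normalized constellations with the RANSAC matcher."""
    return RansacMatcher(cfg).match(spots_a, mask_a, spots_b, mask_b,
                                    seed=seed)
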