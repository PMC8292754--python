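"""Triangle-voting constellation matcher (Groth-style).

Each constellation is reduced to the set of triangles a point forms with
pairs of its nearest neighbours.  A triangle is summarized by similarity-
invariant features — the ratio of longest to shortest side, the cosine of
the angle between those two sides, and the angle from the triangle
centroid to the vertex they share — plus the log perimeter (which changes
by the log magnification under scaling) and the traversal handedness.

Matching proceeds in stages:

1. candidate triangle pairs are found with two k-d trees (mutual
   membership of each other's ``mutual_k`` nearest neighbours in feature
   space);
2. candidates must pass the feature-tolerance test (squared ratio and
   cosine differences below the summed squared tolerances propagated
   from the positional tolerance epsilon) and have equal handedness;
3. the centroid-angle window (10 degrees) and the log-magnification
   window (1.5 standard deviations) are applied; because a whole-pattern
   rotation or growth shifts *every* true pair by the same amount, both
   windows are re-centred on robust (median/MAD) estimates of the global
   rotation and log magnification and the selection is repeated;
4. for each triangle the candidate with the lowest tolerance-normalized
   feature difference is kept;
5. every matched triangle pair votes for its three vertex pairs; vertex
   pairs are assigned in descending vote order until the votes collapse
   (drop by ``vote_drop_factor``) or run out, pairs that would reuse an
   already-assigned point being skipped;
6. the whole procedure is re-run on the matched points only; if the
   second round assigns fewer pairs, the pair of constellations is
   declared impossible to match.

The vote-assignment loop is described in the literature in one sentence
that admits two readings of both the vote-collapse baseline (relative to
the first pair or to the preceding pair) and the conflict rule (stop or
skip).  Under the strict reading (first-pair baseline, stop at the first
conflict) the assignment rarely survives realistic re-capture noise, so
the lenient reading is the default; both are available in
:class:`GrothConfig` (``drop_baseline``, ``reuse_policy``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .errors import TooFewSpotsError
from .results import MatchResult
from .spots import Correspondence, SpotSet

__all__ = [
    "GrothConfig",
    "GrothTriangle",
    "TriangleSet",
    "dedupe_spots",
    "build_triangles_groth",
    "mutual_nearest",
    "match_triangles",
    "vote_and_assign",
    "groth_match",
    "GrothMatcher",
]

ALL_FILTERS = ("tolerance", "handedness", "angle", "magnification")


@dataclass
class GrothConfig:
    epsilon: float = 0.0075         # positional tolerance, fish-length units
    knn: int = 25                   # neighbours considered per point
    max_angle_diff: float = 10.0    # centroid-angle agreement, degrees
    magnification_sd: float = 1.5   # SD window for log-magnification
    vote_drop_factor: float = 2.0   # votes collapse when below prev/this
    score_threshold: float = 6.5    # accept scores at or above this
    angle_feature_weight: float = 0.25  # k-d tree weight of the angle, rad
    mutual_k: int = 6               # mutual neighbourhood size for pairing
    consistency_recentring: bool = True  # re-centre angle/mag windows
    drop_baseline: str = "previous"      # or "first"
    reuse_policy: str = "skip"           # or "stop"
    verification: str = "iterate"        # or "two_round"
    max_verification_rounds: int = 8
    verification_skip_below: float = 3.0  # hopeless-score short-circuit

    def __post_init__(self):
        if min(self.epsilon, self.knn, self.max_angle_diff,
               self.magnification_sd, self.vote_drop_factor,
               self.angle_feature_weight, self.mutual_k) <= 0:
            raise ValueError("all numeric GrothConfig fields must be positive")
        if self.drop_baseline not in ("previous", "first"):
            raise ValueError("drop_baseline must be 'previous' or 'first'")
        if self.reuse_policy not in ("skip", "stop"):
            raise ValueError("reuse_policy must be 'skip' or 'stop'")
        if self.verification not in ("iterate", "two_round"):
            raise ValueError("verification must be 'iterate' or 'two_round'")


@dataclass(frozen=True)
class GrothTriangle:
    """One triangle with its invariant features (mostly for inspection)."""

    vertices: tuple[int, int, int]  # (shared, short end, long end)
    log_perimeter: float
    handedness: int
    ratio: float
    ratio_tolerance: float
    cosine: float
    cosine_tolerance: float
    centroid_angle: float           # degrees


class TriangleSet:
    """Vectorized triangle table for one constellation.

    ``ordered`` holds vertex indices as (shared vertex of shortest and
    longest side, other end of shortest side, other end of longest side).
    """

    def __init__(self, ordered, ratio, cosine, log_per, handed,
                 angle_deg, tol_r2, tol_c2, angle_weight: float = 0.25):
        self.ordered = ordered
        self.ratio = ratio
        self.cosine = cosine
        self.log_per = log_per
        self.handed = handed
        self.angle_deg = angle_deg
        self.tol_r2 = tol_r2
        self.tol_c2 = tol_c2
        # feature space for the k-d trees; the angle is expressed in
        # radians and down-weighted so that a legitimate whole-pattern
        # rotation (up to max_angle_diff) does not dominate the metric
        self.features = np.column_stack(
            [ratio, cosine, angle_weight * np.radians(angle_deg)])
        self._tree = None
        self._self_kth = {}

    def __len__(self) -> int:
        return len(self.ratio)

    def __getitem__(self, i: int) -> GrothTriangle:
        return GrothTriangle(
            vertices=tuple(int(v) for v in self.ordered[i]),
            log_perimeter=float(self.log_per[i]),
            handedness=int(self.handed[i]),
            ratio=float(self.ratio[i]),
            ratio_tolerance=float(math.sqrt(self.tol_r2[i])),
            cosine=float(self.cosine[i]),
            cosine_tolerance=float(math.sqrt(self.tol_c2[i])),
            centroid_angle=float(self.angle_deg[i]))

    def __iter__(self):
        return (self[i] for i in range(len(self)))

    @property
    def tree(self) -> cKDTree:
        if self._tree is None:
            self._tree = cKDTree(self.features)
        return self._tree

    def self_kth_distance(self, k: int) -> np.ndarray:
        """Distance of each triangle to its k-th neighbour within the set.

        Cached; used as a local density scale for reciprocal candidate
        pairing across two sets.
        """
        if k not in self._self_kth:
            kk = min(k + 1, len(self))
            d, _ = self.tree.query(self.features, k=kk, eps=0.05)
            d = d.reshape(len(self), -1)
            self._self_kth[k] = d[:, -1]
        return self._self_kth[k]


def dedupe_spots(spots: SpotSet, epsilon: float) -> tuple[SpotSet, np.ndarray]:
    """Greedily drop any spot within 3*epsilon of an already-kept spot.

    Returns the thinned constellation and the kept original indices.
    """
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    keep: list[int] = []
    limit = 3.0 * epsilon
    for i, p in enumerate(spots.xy):
        if all(np.hypot(*(spots.xy[j] - p)) >= limit for j in keep):
            keep.append(i)
    idx = np.asarray(keep, dtype=int)
    return spots.select(idx), idx


_COMB_CACHE: dict[int, np.ndarray] = {}


def _all_triples(n: int) -> np.ndarray:
    tri = _COMB_CACHE.get(n)
    if tri is None:
        i, j = np.triu_indices(n, k=1)
        pairs = np.column_stack([i, j])
        out = []
        for a in range(n - 2):
            sel = pairs[(pairs[:, 0] > a)]
            out.append(np.column_stack([np.full(len(sel), a), sel]))
        tri = np.vstack(out)
        if len(_COMB_CACHE) < 128:
            _COMB_CACHE[n] = tri
    return tri


def _neighbour_triplets(xy: np.ndarray, knn: int) -> np.ndarray:
    """Unique vertex triples from each point and pairs of its neighbours."""
    n = len(xy)
    k = min(knn + 1, n)
    if k >= n:        # neighbourhoods cover everything: all triples
        return _all_triples(n)
    _, nbrs = cKDTree(xy).query(xy, k=k)
    nbrs = np.atleast_2d(nbrs)
    triplets = []
    for i in range(n):
        others = nbrs[i][nbrs[i] != i]
        if len(others) < 2:
            continue
        ii, jj = np.triu_indices(len(others), k=1)
        t = np.column_stack([np.full(len(ii), i), others[ii], others[jj]])
        triplets.append(t)
    if not triplets:
        return np.empty((0, 3), dtype=int)
    tri = np.vstack(triplets)
    tri = np.sort(tri, axis=1)
    # dedupe by vertex set via integer packing (much faster than a
    # row-wise unique on small index triples)
    packed = (tri[:, 0].astype(np.int64) * n + tri[:, 1]) * n + tri[:, 2]
    _, first = np.unique(packed, return_index=True)
    return tri[np.sort(first)]


# lookup tables: side k joins vertices k and (k+1) % 3; for a (shortest,
# longest) side pair, which vertex is shared and which are the other ends
_SHARED = np.zeros((3, 3), dtype=int)
_END_SHORT = np.zeros((3, 3), dtype=int)
_END_LONG = np.zeros((3, 3), dtype=int)
for _s in range(3):
    for _l in range(3):
        if _s == _l:
            continue
        vs = {_s, (_s + 1) % 3}
        vl = {_l, (_l + 1) % 3}
        _SHARED[_s, _l] = (vs & vl).pop()
        _END_SHORT[_s, _l] = (vs - vl).pop()
        _END_LONG[_s, _l] = (vl - vs).pop()


def build_triangles_groth(spots: SpotSet, cfg: GrothConfig | None = None
                          ) -> TriangleSet:
    """Build the triangle table for one (deduplicated) constellation.

    No side-ratio or cosine pruning is applied: spot patterns are often
    close to linear, and pruning elongated triangles starves small
    constellations.  Triangle count is limited by the ``knn`` rule instead.
    """
    cfg = cfg or GrothConfig()
    if len(spots) < 3:
        raise TooFewSpotsError(f"need >= 3 spots, have {len(spots)}")
    tri = _neighbour_triplets(spots.xy, cfg.knn)
    p = spots.xy[tri]                              # (m, 3, 2)
    # side k joins vertices k and k+1
    side_vec = p[:, [1, 2, 0], :] - p              # (m, 3, 2)
    side_len = np.hypot(side_vec[..., 0], side_vec[..., 1])
    order = np.argsort(side_len, axis=1, kind="stable")
    si, li = order[:, 0], order[:, 2]
    rows = np.arange(len(tri))
    s_min = side_len[rows, si]
    s_max = side_len[rows, li]

    shared = tri[rows, _SHARED[si, li]]
    end_short = tri[rows, _END_SHORT[si, li]]
    end_long = tri[rows, _END_LONG[si, li]]
    a = spots.xy[shared]
    b = spots.xy[end_short]
    c = spots.xy[end_long]
    v_ab = b - a
    v_ac = c - a
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = s_max / s_min
        cosine = np.einsum("ij,ij->i", v_ab, v_ac) / (s_min * s_max)
    cosine = np.clip(cosine, -1.0, 1.0)
    cross = v_ab[:, 0] * v_ac[:, 1] - v_ab[:, 1] * v_ac[:, 0]
    handed = np.sign(cross).astype(int)
    log_per = np.log(side_len.sum(axis=1))
    centroid = p.mean(axis=1)
    rel = a - centroid
    angle_deg = np.degrees(np.arctan2(rel[:, 1], rel[:, 0]))

    # first-order tolerance propagation from the positional tolerance
    eps2 = cfg.epsilon**2
    f = eps2 * (1.0 / s_max**2 - cosine / (s_max * s_min) + 1.0 / s_min**2)
    tol_r2 = 2.0 * ratio**2 * f
    sin2 = 1.0 - cosine**2
    tol_c2 = sin2 * f + 3.0 * cosine**2 * f**2

    ordered = np.column_stack([shared, end_short, end_long])
    return TriangleSet(ordered, ratio, cosine, log_per, handed,
                       angle_deg, tol_r2, tol_c2,
                       angle_weight=cfg.angle_feature_weight)


def mutual_nearest(tri_a: TriangleSet, tri_b: TriangleSet
                   ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Strict mutual nearest-neighbour triangle pairs in feature space.

    Computed with the two k-d trees; equals the brute-force all-pairs
    mutual-nearest-neighbour set.  Returns (indices into A, indices into
    B, feature distances).
    """
    d_ab, nn_b = tri_b.tree.query(tri_a.features)
    _, nn_a = tri_a.tree.query(tri_b.features)
    a_idx = np.arange(len(tri_a))
    mutual = nn_a[nn_b] == a_idx
    return a_idx[mutual], nn_b[mutual], d_ab[mutual]


def _mutual_candidates(tri_a: TriangleSet, tri_b: TriangleSet, k: int
                       ) -> tuple[np.ndarray, np.ndarray]:
    """Candidate pairs: j among i's k nearest and i among j's k nearest."""
    ka = min(k, len(tri_b))
    # slightly approximate neighbour lists are fine here: these are only
    # candidates, and the tolerance/window filters clean up afterwards
    db, nb = tri_b.tree.query(tri_a.features, k=ka, eps=0.05)
    db = db.reshape(len(tri_a), -1)
    nb = nb.reshape(len(tri_a), -1)
    I = np.repeat(np.arange(len(tri_a)), nb.shape[1])
    J = nb.ravel()
    # reciprocity: keep (i, j) only when i is about as close to j as j's
    # own k-th neighbour — a cached-density stand-in for querying the
    # reverse direction, at half the cost
    mut = db.ravel() <= tri_b.self_kth_distance(k)[J]
    return I[mut], J[mut]


def _wrap_deg(x: np.ndarray) -> np.ndarray:
    return (x + 180.0) % 360.0 - 180.0


class _CandidateTable:
    """Per-candidate-pair feature differences, computed once."""

    def __init__(self, tri_a, tri_b, I, J):
        self.I = I
        self.J = J
        self.dr2 = (tri_a.ratio[I] - tri_b.ratio[J]) ** 2
        self.dc2 = (tri_a.cosine[I] - tri_b.cosine[J]) ** 2
        self.tr2 = tri_a.tol_r2[I] + tri_b.tol_r2[J]
        self.tc2 = tri_a.tol_c2[I] + tri_b.tol_c2[J]
        self.handed_eq = tri_a.handed[I] == tri_b.handed[J]
        self.diff = _wrap_deg(tri_a.angle_deg[I] - tri_b.angle_deg[J])
        self.lm = tri_a.log_per[I] - tri_b.log_per[J]


def _apply_windows(tab: "_CandidateTable", cfg, filters,
                   ang_center, ang_halfwidth, lp_center, lp_halfwidth):
    """Masks + per-A-triangle best selection on a fixed candidate list."""
    ok = np.ones(len(tab.I), dtype=bool)
    if "tolerance" in filters:
        ok &= (tab.dr2 < tab.tr2) & (tab.dc2 < tab.tc2)
    if "handedness" in filters:
        ok &= tab.handed_eq
    if "angle" in filters:
        ok &= np.abs(_wrap_deg(tab.diff - ang_center)) <= ang_halfwidth
    if "magnification" in filters and lp_center is not None:
        ok &= np.abs(tab.lm - lp_center) <= lp_halfwidth
    I, J = tab.I[ok], tab.J[ok]
    with np.errstate(invalid="ignore", divide="ignore"):
        nd = tab.dr2[ok] / tab.tr2[ok] + tab.dc2[ok] / tab.tc2[ok]
    nd = np.nan_to_num(nd, nan=0.0, posinf=0.0)
    # the candidate with the lowest tolerance-normalized difference wins
    order = np.lexsort((nd, I))
    I, J, nd = I[order], J[order], nd[order]
    keep = np.ones(len(I), dtype=bool)
    keep[1:] = I[1:] != I[:-1]
    return I[keep], J[keep], nd[keep]


def match_triangles(tri_a: TriangleSet, tri_b: TriangleSet,
                    cfg: GrothConfig | None = None,
                    filters: tuple[str, ...] = ALL_FILTERS
                    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Pair triangles of two constellations and prune unlikely pairs.

    Candidates come from the dual k-d trees (mutual ``mutual_k``
    neighbourhoods; with ``mutual_k=1`` this is the strict mutual-NN
    set).  The pruning filters — feature-tolerance test, same
    handedness, centroid-angle agreement within ``max_angle_diff``,
    log-magnification within ``magnification_sd`` standard deviations —
    each only remove candidate pairs.  When ``consistency_recentring``
    is on, the angle and magnification windows are re-centred on robust
    estimates of the global rotation and growth and applied again, which
    prunes pairs inconsistent with the dominant alignment.
    """
    cfg = cfg or GrothConfig()
    I0, J0 = _mutual_candidates(tri_a, tri_b, cfg.mutual_k)
    if len(I0) == 0:
        return I0, J0, np.empty(0)
    tab = _CandidateTable(tri_a, tri_b, I0, J0)
    if cfg.consistency_recentring:
        # magnification consistency is enforced by the recentred second
        # pass below (median/MAD version of the 1.5-SD rule)
        lp_c, lp_hw = None, None
    else:
        lp_c = float(tab.lm.mean()) if "magnification" in filters else None
        lp_hw = cfg.magnification_sd * float(tab.lm.std()) + 1e-12
    I, J, nd = _apply_windows(
        tab, cfg, filters,
        ang_center=0.0, ang_halfwidth=cfg.max_angle_diff,
        lp_center=lp_c, lp_halfwidth=lp_hw)
    if cfg.consistency_recentring and len(I) >= 6:
        diff = _wrap_deg(tri_a.angle_deg[I] - tri_b.angle_deg[J])
        lm = tri_a.log_per[I] - tri_b.log_per[J]
        ang_c = float(np.median(diff))
        lp_c = float(np.median(lm))
        ang_sd = 1.4826 * float(np.median(np.abs(diff - ang_c)))
        lp_sd = 1.4826 * float(np.median(np.abs(lm - lp_c)))
        I2, J2, nd2 = _apply_windows(
            tab, cfg, filters,
            ang_center=ang_c,
            ang_halfwidth=max(cfg.magnification_sd * ang_sd, 1.0),
            lp_center=lp_c if "magnification" in filters else None,
            lp_halfwidth=max(cfg.magnification_sd * lp_sd, 0.01))
        if len(I2) >= 6:
            I, J, nd = I2, J2, nd2
    return I, J, nd


def vote_and_assign(tri_a: TriangleSet, tri_b: TriangleSet,
                    matches: tuple[np.ndarray, np.ndarray, np.ndarray],
                    cfg: GrothConfig | None = None
                    ) -> tuple[Correspondence, dict]:
    """Tally vertex-pair votes from matched triangles and assign greedily.

    Pairs are taken in descending vote order (ties by summed normalized
    triangle difference, then lexicographic index).  Assignment ends
    when the votes collapse by ``vote_drop_factor`` relative to the
    baseline (the preceding pair by default, the first pair under
    ``drop_baseline='first'``) or drop to zero.  A pair that would reuse
    an already-assigned point is skipped (``reuse_policy='skip'``) or
    ends the assignment (``'stop'``).
    """
    cfg = cfg or GrothConfig()
    ia, ib, dist = matches
    if len(ia) == 0:
        return Correspondence([]), {"votes": {}, "total_votes": 0}
    pa = tri_a.ordered[ia].reshape(-1)        # 3 vertex pairs per triangle
    pb = tri_b.ordered[ib].reshape(-1)
    pdist = np.repeat(dist, 3)
    n_b = int(pb.max()) + 1
    packed = pa.astype(np.int64) * n_b + pb
    uniq_packed, inv = np.unique(packed, return_inverse=True)
    uniq = np.column_stack([uniq_packed // n_b, uniq_packed % n_b])
    votes = np.bincount(inv, minlength=len(uniq))
    dsum = np.bincount(inv, weights=pdist, minlength=len(uniq))
    order = np.lexsort((uniq[:, 1], uniq[:, 0], dsum, -votes))

    assigned: list[tuple[int, int]] = []
    used_a: set[int] = set()
    used_b: set[int] = set()
    baseline = votes[order[0]]
    for k in order:
        v = votes[k]
        if v <= 0 or v * cfg.vote_drop_factor < baseline:
            break
        a, b = int(uniq[k, 0]), int(uniq[k, 1])
        if a in used_a or b in used_b:
            if cfg.reuse_policy == "stop":
                break
            continue
        assigned.append((a, b))
        used_a.add(a)
        used_b.add(b)
        if cfg.drop_baseline == "previous":
            baseline = v
    tally = dict(zip(zip(uniq[:, 0].tolist(), uniq[:, 1].tolist()),
                     votes.tolist()))
    return Correspondence(assigned), {"votes": tally,
                                      "total_votes": int(votes.sum())}


class GrothMatcher:
    """Reusable matcher with per-constellation preparation caching."""

    def __init__(self, cfg: GrothConfig | None = None):
        self.cfg = cfg or GrothConfig()

    def prepare(self, spots: SpotSet):
        deduped, kept = dedupe_spots(spots, self.cfg.epsilon)
        if len(deduped) < 3:
            return deduped, kept, None
        return deduped, kept, build_triangles_groth(deduped, self.cfg)

    def _run_round(self, tri_a, tri_b):
        matches = match_triangles(tri_a, tri_b, self.cfg)
        return vote_and_assign(tri_a, tri_b, matches, self.cfg)

    def match_prepared(self, prep_a, prep_b) -> MatchResult:
        spots_a, kept_a, tri_a = prep_a
        spots_b, kept_b, tri_b = prep_b
        if tri_a is None or tri_b is None:
            return MatchResult(Correspondence([]), None, False,
                               diagnostics={"reason": "too few spots"})
        corr1, diag1 = self._run_round(tri_a, tri_b)
        if len(corr1) < 3:
            return MatchResult(Correspondence([]), 0.0, False,
                               diagnostics={"reason": "no stable votes",
                                            "rounds": 1})
        # verification can only shrink the matched set, so the round-1
        # score is an upper bound; comparisons that cannot reach even a
        # marginal score are rejected without the verification rounds
        captured1 = sum(diag1["votes"].get(p, 0) for p in corr1)
        bound = len(corr1) * captured1 / max(diag1["total_votes"], 1)
        if bound < self.cfg.verification_skip_below:
            mapped = [(int(kept_a[a]), int(kept_b[b])) for a, b in corr1]
            return MatchResult(Correspondence(mapped), float(bound), False,
                               diagnostics={"reason": "below verification "
                                                      "floor",
                                            "rounds": 1,
                                            "round1": len(corr1)})
        # verification: re-run the whole procedure on the matched points;
        # a verified match must reproduce its own pair set.  The strict
        # two-round variant rejects on any shrinkage; the default iterates,
        # pruning unstable pairs until the set is stable (or collapses).
        current = list(corr1)
        rounds = 1
        verified = False
        max_rounds = (2 if self.cfg.verification == "two_round"
                      else self.cfg.max_verification_rounds)
        while rounds < max_rounds:
            rounds += 1
            sel_a = np.array([a for a, _ in current])
            sel_b = np.array([b for _, b in current])
            tri_a2 = build_triangles_groth(spots_a.select(sel_a), self.cfg)
            tri_b2 = build_triangles_groth(spots_b.select(sel_b), self.cfg)
            corr_v, _ = self._run_round(tri_a2, tri_b2)
            if len(corr_v) >= len(current):
                verified = True
                break
            if self.cfg.verification == "two_round" or len(corr_v) < 3:
                break
            # keep only pairs the verification round reproduced
            reproduced = {(int(sel_a[x]), int(sel_b[y])) for x, y in corr_v}
            survivors = [(a, b) for a, b in current
                         if (int(a), int(b)) in reproduced]
            if len(survivors) < 3:
                current = survivors
                break
            current = survivors
        if not verified or len(current) < 3:
            return MatchResult(Correspondence([]), 0.0, False,
                               diagnostics={"reason": "verification dropout",
                                            "round1": len(corr1),
                                            "final": len(current),
                                            "rounds": rounds})
        captured = sum(diag1["votes"].get(p, 0) for p in current)
        score = len(current) * captured / max(diag1["total_votes"], 1)
        mapped = [(int(kept_a[a]), int(kept_b[b])) for a, b in current]
        return MatchResult(Correspondence(mapped), float(score),
                           score >= self.cfg.score_threshold,
                           diagnostics={"rounds": rounds,
                                        "round1": len(corr1),
                                        "verified": len(current)})

    def match(self, spots_a: SpotSet, spots_b: SpotSet) -> MatchResult:
        return self.match_prepared(self.prepare(spots_a),
                                   self.prepare(spots_b))


def groth_match(spots_a: SpotSet, spots_b: SpotSet,
                cfg: GrothConfig | None = None) -> MatchResult:
    """Match two normalized constellations with the triangle-voting matcher."""
    return GrothMatcher(cfg).match(spots_a, spots_b)
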