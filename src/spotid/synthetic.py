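"""Synthetic data generation for every stage of the pipeline.

Three families of synthetic inputs are produced:

* rendered fish photographs with ground-truth body and spot masks, emulating
  a dark, spotted, fish-shaped body photographed on a light background with
  optional distractors (a ruler-like stripe, debris, a shadow gradient);
* spot constellations and perturbed re-captures with known ground-truth
  correspondence, emulating re-photographing the same individual after
  rotation, growth, positional jitter and spot turnover;
* capture histories from a survival/capture process, with optional tag loss
  that fragments observed identities the way lost PIT tags do in the field.

All randomness is driven by one explicit seed per call; no global RNG state.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .errors import ValidationError
from .histories import CaptureHistoryMatrix, CaptureRecord
from .spots import Correspondence, SpotSet

__all__ = [
    "SyntheticFishSpec",
    "PerturbationSpec",
    "PopulationSimSpec",
    "generate_constellation",
    "perturb_constellation",
    "render_fish_image",
    "simulate_capture_histories",
    "inject_tag_loss",
    "observed_history_matrix",
]


@dataclass
class SyntheticFishSpec:
    """Recipe for one rendered fish photograph.

    The body is a horizontally elongated ellipse whose half-width tapers
    toward the tail, giving the mask a bulky head end so that orientation
    is recoverable from pixel statistics.  Intensities follow the
    photographic situation: dark spots on a darker body on a light
    background (``spot_level < body_level < background_level``).
    """

    frame: tuple[int, int] = (2600, 1040)         # (width, height) px
    body_center: tuple[float, float] | None = None  # defaults to frame centre
    body_axes: tuple[float, float] = (950.0, 290.0)  # semi-axes px
    body_rotation: float = 0.0                    # degrees, CCW
    n_spots: int = 30
    spot_radius_range: tuple[float, float] = (16.0, 25.0)  # px
    spot_margin_frac: float = 0.15   # keep spots off the body outline
    background_level: int = 170
    body_level: int = 30
    spot_level: int = 10
    noise_sd: float = 6.0
    taper: float = 0.45        # relative narrowing of the tail end
    distractors: list[str] = field(default_factory=list)
    rng_seed: int = 0

    def __post_init__(self):
        if not (self.spot_level < self.body_level < self.background_level):
            raise ValueError(
                "levels must satisfy spot < body < background")
        if self.body_center is None:
            self.body_center = (self.frame[0] / 2.0, self.frame[1] / 2.0)
        if self.n_spots < 0:
            raise ValueError("n_spots must be non-negative")
        if self.spot_radius_range[1] > min(self.body_axes):
            raise ValueError("spot radius exceeds the minor body axis")
        allowed = {"ruler_stripe", "debris_blob", "shadow_gradient"}
        unknown = set(self.distractors) - allowed
        if unknown:
            raise ValueError(f"unknown distractors: {sorted(unknown)}")


@dataclass
class PerturbationSpec:
    """Similarity transform + noise + spot turnover between two captures.

    Rotation (degrees) and uniform ``scale`` (growth between captures) act
    about the constellation centroid; ``translation`` is added afterwards.
    ``jitter_sd`` is per-coordinate Gaussian positional noise.  A fraction
    ``drop_fraction`` of spots disappears (floor rule) and ``add_count``
    new spots appear, modelling spot turnover.
    """

    rotation: float = 0.0
    scale: float = 1.0
    translation: tuple[float, float] = (0.0, 0.0)
    jitter_sd: float = 0.0
    drop_fraction: float = 0.0
    add_count: int = 0
    rng_seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.drop_fraction <= 1.0:
            raise ValueError("drop_fraction must lie in [0, 1]")
        if self.scale <= 0:
            raise ValueError("scale must be positive")
        if self.add_count < 0:
            raise ValueError("add_count must be non-negative")


@dataclass
class PopulationSimSpec:
    """Survival/capture process for a population of marked individuals.

    ``phi`` is the per-interval survival probability, ``p`` the per-occasion
    capture probability, and ``tag_loss_rate`` the per-recapture probability
    that the tag is absent so the individual is recorded under a fresh id.
    """

    n_individuals: int = 300
    n_occasions: int = 15
    phi: float = 0.78
    p: float = 0.53
    tag_loss_rate: float = 0.07
    rng_seed: int = 0

    def __post_init__(self):
        for name in ("phi", "p", "tag_loss_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.n_individuals < 1 or self.n_occasions < 2:
            raise ValueError("need >= 1 individual and >= 2 occasions")


# ---------------------------------------------------------------------------
# constellations


def _default_radius_range(frame):
    lo = 0.008 * max(frame)
    return (lo, 1.5 * lo)


def generate_constellation(n_spots: int,
                           frame: tuple[float, float] = (1.0, 0.4),
                           seed: int = 0,
                           radius_range: tuple[float, float] | None = None,
                           min_separation: float | None = None,
                           within_ellipse: tuple | None = None,
                           normalized: bool | None = None) -> SpotSet:
    """Draw ``n_spots`` non-overlapping spots uniformly inside ``frame``.

    Spots are placed by dart throwing with a minimum pairwise separation of
    twice the maximum spot radius, so synthetic spots never merge.  If
    ``within_ellipse = ((cx, cy), (a, b))`` is given, spots are confined to
    that ellipse (a fish-body region) instead of the full rectangle.
    Deterministic given ``seed``.
    """
    if n_spots < 0:
        raise ValueError("n_spots must be non-negative")
    w, h = float(frame[0]), float(frame[1])
    if w <= 0 or h <= 0:
        raise ValueError("frame dimensions must be positive")
    if normalized is None:
        normalized = max(w, h) <= 2.0  # unit-frame constellations
    if n_spots == 0:
        return SpotSet.empty(frame=(w, h), normalized=normalized)
    if radius_range is None:
        radius_range = _default_radius_range((w, h))
    r_lo, r_hi = radius_range
    if min_separation is None:
        min_separation = 2.0 * r_hi

    rng = np.random.default_rng(seed)
    placed = np.empty((0, 2))
    radii = []
    attempts = 0
    max_attempts = 20000 * max(n_spots, 1)
    while len(radii) < n_spots:
        attempts += 1
        if attempts > max_attempts:
            raise RuntimeError(
                f"could not place {n_spots} spots with separation "
                f"{min_separation:g} in frame {(w, h)}")
        r = rng.uniform(r_lo, r_hi)
        if within_ellipse is not None:
            (cx, cy), (a, b) = within_ellipse
            # sample uniformly in the ellipse shrunk by the spot radius
            u = rng.uniform(0, 2 * math.pi)
            rad = math.sqrt(rng.uniform())
            x = cx + (a - r) * rad * math.cos(u)
            y = cy + (b - r) * rad * math.sin(u)
        else:
            x = rng.uniform(r, w - r)
            y = rng.uniform(r, h - r)
        if len(placed) and np.any(
                np.hypot(*(placed - [x, y]).T) < min_separation):
            continue
        placed = np.vstack([placed, [x, y]])
        radii.append(r)
    sizes = math.pi * np.asarray(radii) ** 2
    return SpotSet(placed, sizes, frame=(w, h), normalized=normalized)


def perturb_constellation(spots: SpotSet, spec: PerturbationSpec
                          ) -> tuple[SpotSet, Correspondence]:
    """Re-capture simulation: similarity transform + jitter + spot turnover.

    Returns the perturbed constellation and the ground-truth correspondence
    mapping surviving original indices to indices in the new set.  Dropped
    spots have no entry; added spots have no pre-image.
    """
    if len(spots) == 0:
        raise ValueError("cannot perturb an empty constellation")
    rng = np.random.default_rng(spec.rng_seed)

    n = len(spots)
    n_drop = int(math.floor(n * spec.drop_fraction))
    keep = np.sort(rng.choice(n, size=n - n_drop, replace=False))

    theta = math.radians(spec.rotation)
    rot = np.array([[math.cos(theta), -math.sin(theta)],
                    [math.sin(theta), math.cos(theta)]])
    centroid = spots.xy.mean(axis=0)
    new_xy = (spots.xy[keep] - centroid) @ (spec.scale * rot).T + centroid
    new_xy = new_xy + np.asarray(spec.translation, dtype=float)
    if spec.jitter_sd > 0:
        new_xy = new_xy + rng.normal(0.0, spec.jitter_sd, size=new_xy.shape)
    new_sizes = spots.sizes[keep] * spec.scale**2

    pairs = [(int(orig), j) for j, orig in enumerate(keep)]

    if spec.add_count > 0:
        # new spots are distinct markings: keep the same minimum
        # separation from existing spots as the generator enforces
        lo = new_xy.min(axis=0)
        hi = new_xy.max(axis=0)
        min_sep = 2.0 * np.sqrt(new_sizes.max() / math.pi)
        extras = []
        tries = 0
        while len(extras) < spec.add_count and tries < 10000:
            tries += 1
            cand = rng.uniform(lo, hi)
            pool = (np.vstack([new_xy] + [np.array(extras)])
                    if extras else new_xy)
            if np.min(np.hypot(*(pool - cand).T)) >= min_sep:
                extras.append(cand)
        extra_xy = np.array(extras).reshape(-1, 2)
        s_lo, s_hi = float(new_sizes.min()), float(new_sizes.max())
        extra_sizes = rng.uniform(s_lo, max(s_hi, s_lo * (1 + 1e-9)),
                                  size=len(extra_xy))
        new_xy = np.vstack([new_xy, extra_xy])
        new_sizes = np.concatenate([new_sizes, extra_sizes])

    out = SpotSet(new_xy, new_sizes, frame=spots.frame,
                  normalized=spots.normalized,
                  length_scale=spots.length_scale)
    return out, Correspondence(pairs)


# ---------------------------------------------------------------------------
# rendering


def _body_mask_for(spec: SyntheticFishSpec) -> np.ndarray:
    """Tapered-ellipse body: bulky head at -x (before rotation)."""
    w, h = spec.frame
    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    cx, cy = spec.body_center
    th = math.radians(spec.body_rotation)
    # coordinates in the body frame (u along major axis, v across)
    u = (xx - cx) * math.cos(th) + (yy - cy) * math.sin(th)
    v = -(xx - cx) * math.sin(th) + (yy - cy) * math.cos(th)
    a, b = spec.body_axes
    un = u / a
    with np.errstate(invalid="ignore"):
        width = np.where(np.abs(un) <= 1.0,
                         np.sqrt(np.clip(1 - un**2, 0, 1))
                         * (1 - spec.taper * (un + 1) / 2.0),
                         0.0)
    return (np.abs(un) <= 1.0) & (np.abs(v) <= b * width)


def render_fish_image(spec: SyntheticFishSpec
                      ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Render a photograph-like image plus ground-truth masks.

    Returns ``(image, body_mask, spot_mask)`` where image is H x W x 3
    uint8 and the masks are boolean arrays of the same frame.  The spot
    mask is a subset of the body mask by construction.  Deterministic
    given ``spec.rng_seed``.
    """
    rng = np.random.default_rng(spec.rng_seed)
    w, h = spec.frame
    body = _body_mask_for(spec)

    # spots are an intrinsic property of the fish: sample their centres in
    # the *unrotated* body frame (so the same seed renders the same spot
    # pattern in any pose), then rotate them with the body
    spot_mask = np.zeros_like(body)
    if spec.n_spots > 0:
        upright = (spec if spec.body_rotation == 0.0 else
                   SyntheticFishSpec(**{**spec.__dict__, "body_rotation": 0.0,
                                        "distractors": list(spec.distractors)}))
        base = _body_mask_for(upright)
        dist = ndimage.distance_transform_edt(base)
        r_lo, r_hi = spec.spot_radius_range
        # spots sit on the flank, away from the dorsal/ventral margins
        margin = spec.spot_margin_frac * min(spec.body_axes)
        ys, xs = np.nonzero(dist > r_hi + margin)
        if len(ys) == 0:
            raise ValueError("body too small for the requested spot radius")
        order = rng.permutation(len(ys))
        centres, radii = [], []
        min_sep = 2.0 * r_hi
        for idx in order:
            if len(centres) == spec.n_spots:
                break
            x, y = float(xs[idx]), float(ys[idx])
            r = rng.uniform(r_lo, r_hi)
            if dist[int(y), int(x)] <= r + margin:
                continue
            if centres and np.any(
                    np.hypot(*(np.array(centres) - [x, y]).T) < min_sep):
                continue
            centres.append([x, y])
            radii.append(r)
        if centres:
            th = math.radians(spec.body_rotation)
            c = np.asarray(spec.body_center)
            rot = np.array([[math.cos(th), -math.sin(th)],
                            [math.sin(th), math.cos(th)]])
            centres = (np.asarray(centres) - c) @ rot.T + c
        yy, xx = np.mgrid[0:h, 0:w].astype(float)
        for (x, y), r in zip(centres, radii):
            spot_mask |= (xx - x) ** 2 + (yy - y) ** 2 <= r**2
        spot_mask &= body

    img = np.full((h, w), float(spec.background_level))
    img[body] = spec.body_level
    img[spot_mask] = spec.spot_level

    if "ruler_stripe" in spec.distractors:
        # a dark ruler with bright tick marks along the bottom edge; its
        # blurred core stays below the body threshold
        band_h = int(0.12 * h)
        band = np.full((band_h, w), 50.0)
        tick_w = max(4, int(0.004 * w))
        for x0 in range(0, w, max(8 * tick_w, 1)):
            band[:, x0:x0 + tick_w] = 230
        img[h - band_h:, :] = band
    if "debris_blob" in spec.distractors:
        # large dark debris; under the heavy body blur these survive as
        # candidate components and can hijack the central-component rule
        yy, xx = np.mgrid[0:h, 0:w].astype(float)
        for _ in range(5):
            bx = rng.uniform(0.15 * w, 0.85 * w)
            by = rng.uniform(0.15 * h, 0.85 * h)
            br = rng.uniform(0.04, 0.08) * max(w, h)
            blob = (xx - bx) ** 2 + (yy - by) ** 2 <= br**2
            img[blob & ~body] = rng.uniform(20, 45)
    if "shadow_gradient" in spec.distractors:
        grad = np.linspace(1.0, 0.55, w)[None, :]
        img = img * grad

    img = img + rng.normal(0.0, spec.noise_sd, size=img.shape)
    img = ndimage.gaussian_filter(img, 1.2)
    img = np.clip(img, 0, 255).astype(np.uint8)
    image = np.repeat(img[:, :, None], 3, axis=2)
    return image, body, spot_mask


def aligned_body_mask(half_depth: float = 0.16,
                      taper: float = 0.45) -> np.ndarray:
    """Fish-body silhouette directly in the canonical aligned raster.

    The body spans x in [0, 1] with half-width profile
    ``half_depth * sqrt(1 - u^2) * (1 - taper * (u + 1) / 2)`` (u = 2x - 1),
    i.e. an ellipse tapering toward the tail, centred on y = 0.  Used to
    pair synthetic constellations with a plausible body mask without
    rendering a photograph.
    """
    from .prep import RASTER_PAD_X, RASTER_SCALE, RASTER_SHAPE
    h, w = RASTER_SHAPE
    cols = (np.arange(w) - RASTER_PAD_X) / RASTER_SCALE
    rows = (np.arange(h) - h / 2.0) / RASTER_SCALE
    u = 2.0 * cols - 1.0
    width = np.where(np.abs(u) <= 1.0,
                     half_depth * np.sqrt(np.clip(1 - u**2, 0, 1))
                     * (1 - taper * (u + 1) / 2.0),
                     -1.0)
    return np.abs(rows)[:, None] <= width[None, :]


# ---------------------------------------------------------------------------
# capture histories


def simulate_capture_histories(spec: PopulationSimSpec) -> CaptureHistoryMatrix:
    """Forward-simulate survival and capture for a marked population.

    Every individual is alive at occasion 1; survival between occasions is
    Bernoulli(phi) and capture of a live individual is Bernoulli(p).
    Individuals never captured are discarded (they are invisible to a
    capture-mark-recapture study), so the returned matrix has at most
    ``n_individuals`` rows, each with a 1 at its first-capture occasion.
    """
    rng = np.random.default_rng(spec.rng_seed)
    n, T = spec.n_individuals, spec.n_occasions
    alive = np.ones(n, dtype=bool)
    y = np.zeros((n, T), dtype=np.int8)
    for t in range(T):
        if t > 0:
            alive &= rng.random(n) < spec.phi
        y[:, t] = alive & (rng.random(n) < spec.p)
    seen = y.any(axis=1)
    ids = [f"ind{i:04d}" for i in np.nonzero(seen)[0]]
    return CaptureHistoryMatrix(y[seen], ids)


def inject_tag_loss(records: list[CaptureRecord], rate: float,
                    seed: int = 0) -> list[CaptureRecord]:
    """Fragment capture records by simulated tag loss.

    At each recapture event, with probability ``rate`` the tag is absent
    and the individual is recorded under a fresh, never-seen observed id
    which then persists until the next loss.  First captures always keep
    their original id.  True ids are retained on the returned records as
    hidden ground truth.
    """
    if not 0.0 <= rate <= 1.0:
        raise ValueError("rate must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    out: list[CaptureRecord] = []
    current: dict[str, str] = {}
    n_fresh = 0
    for rec in sorted(records, key=lambda r: (r.occasion, r.true_id)):
        if rec.true_id not in current:
            current[rec.true_id] = rec.true_id   # first capture: tag intact
        elif rate > 0 and rng.random() < rate:
            n_fresh += 1
            current[rec.true_id] = f"lost{n_fresh:04d}"
        out.append(CaptureRecord(true_id=rec.true_id,
                                 occasion=rec.occasion,
                                 observed_id=current[rec.true_id]))
    return out


def observed_history_matrix(records: list[CaptureRecord],
                            n_occasions: int) -> CaptureHistoryMatrix:
    """Build the observed capture-history matrix, grouping by observed id."""
    by_id: dict[str, np.ndarray] = {}
    for rec in records:
        row = by_id.setdefault(rec.observed_id,
                               np.zeros(n_occasions, dtype=np.int8))
        row[rec.occasion] = 1
    ids = sorted(by_id)
    if not ids:
        raise ValidationError("no capture records given")
    y = np.stack([by_id[i] for i in ids])
    return CaptureHistoryMatrix(y, ids)
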