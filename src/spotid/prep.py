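"""Constellation preparation: contours to (x, y, size), PCA alignment.

Matching operates on *normalized* constellations: the body mask is rotated
so its first principal axis is horizontal, coordinates are divided by the
body length, and x runs from 0 (one end of the fish) to 1 (the other).
The 180-degree ambiguity of the principal axis is resolved with the third
central moment of the mask pixels along the major axis: the orientation
with negative skewness is chosen, which places the tapered (tail) end at
low x for the synthetic body shape.  Coordinates are x right, y down,
0-based pixel centres.

Aligned masks are rasterized into a canonical frame shared by all records
(:data:`RASTER_SHAPE`, :data:`RASTER_SCALE` px per fish-length unit) so
that masks of different photographs can be overlaid directly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from skimage import measure, transform as sktransform

from .errors import DegenerateMaskError
from .spots import SpotSet

#: canonical aligned-mask raster: (height, width), px per unit, x offset px
RASTER_SHAPE = (128, 256)
RASTER_SCALE = 200.0
RASTER_PAD_X = 28.0


@dataclass
class AlignmentInfo:
    """Invertible record of a PCA alignment.

    Raw pixel coordinates ``p`` map to normalized coordinates via
    ``q = (R (p - mean) - offset) / length_scale`` with ``R`` the rotation
    by :attr:`rotation_deg`.
    """

    rotation_deg: float
    mean: np.ndarray
    offset: np.ndarray
    length_scale: float

    @property
    def rotation_matrix(self) -> np.ndarray:
        th = math.radians(self.rotation_deg)
        return np.array([[math.cos(th), -math.sin(th)],
                         [math.sin(th), math.cos(th)]])

    def apply(self, points: np.ndarray) -> np.ndarray:
        points = np.asarray(points, dtype=float)
        rotated = (points - self.mean) @ self.rotation_matrix.T
        return (rotated - self.offset) / self.length_scale

    def invert(self, points: np.ndarray) -> np.ndarray:
        points = np.asarray(points, dtype=float)
        rotated = points * self.length_scale + self.offset
        return rotated @ self.rotation_matrix + self.mean


def spots_from_mask(spot_mask: np.ndarray) -> SpotSet:
    """One spot per connected component: centroid position, pixel count."""
    spot_mask = np.asarray(spot_mask, dtype=bool)
    labels = measure.label(spot_mask)
    xs, ys, sizes = [], [], []
    for region in measure.regionprops(labels):
        cy, cx = region.centroid
        xs.append(cx)
        ys.append(cy)
        sizes.append(float(region.area))
    if not xs:
        return SpotSet.empty(frame=(spot_mask.shape[1], spot_mask.shape[0]))
    xy = np.column_stack([xs, ys])
    return SpotSet(xy, np.asarray(sizes),
                   frame=(spot_mask.shape[1], spot_mask.shape[0]))


def _mask_coords(body_mask) -> tuple[np.ndarray, bool]:
    """Pixel-centre coordinates of a mask given as raster or point array."""
    body_mask = np.asarray(body_mask)
    if body_mask.ndim == 2 and body_mask.shape[1] != 2:
        ys, xs = np.nonzero(body_mask)
        return np.column_stack([xs, ys]).astype(float), True
    if body_mask.ndim == 2 and body_mask.dtype != bool:
        return body_mask.astype(float), False
    ys, xs = np.nonzero(body_mask)
    return np.column_stack([xs, ys]).astype(float), True


def normalized_to_raster(points: np.ndarray) -> np.ndarray:
    """Map normalized (x, y) to canonical raster (col, row) coordinates."""
    points = np.asarray(points, dtype=float)
    out = points * RASTER_SCALE
    out[..., 0] += RASTER_PAD_X
    out[..., 1] += RASTER_SHAPE[0] / 2.0
    return out


def rasterize_aligned_mask(body_mask: np.ndarray,
                           info: AlignmentInfo) -> np.ndarray:
    """Warp a raw body-mask raster into the canonical aligned frame."""
    # canonical raster (col,row) -> normalized -> raw pixel coordinates
    s = RASTER_SCALE
    norm = sktransform.AffineTransform(
        matrix=np.array([[1 / s, 0, -RASTER_PAD_X / s],
                         [0, 1 / s, -RASTER_SHAPE[0] / (2 * s)],
                         [0, 0, 1]]))
    R = np.eye(3)
    R[:2, :2] = info.rotation_matrix
    to_raw = sktransform.AffineTransform(
        matrix=np.array([[1, 0, info.mean[0]],
                         [0, 1, info.mean[1]],
                         [0, 0, 1]])
        @ R.T
        @ np.array([[info.length_scale, 0, info.offset[0]],
                    [0, info.length_scale, info.offset[1]],
                    [0, 0, 1]]))
    # warp's inverse_map goes from output (canonical) to input (raw) coords
    warped = sktransform.warp(np.asarray(body_mask, dtype=float),
                              inverse_map=(norm + to_raw),
                              output_shape=RASTER_SHAPE, order=0,
                              mode="constant", cval=0.0)
    return warped > 0.5


def pca_align(spots: SpotSet, body_mask
              ) -> tuple[SpotSet, np.ndarray, AlignmentInfo]:
    """Align a constellation and its body mask to the canonical frame.

    The mask's first principal axis is rotated to the horizontal, the
    orientation sign is fixed by requiring negative skewness of the pixel
    distribution along that axis, and all coordinates are divided by the
    mask extent along the axis (the fish length).  ``body_mask`` may be a
    boolean raster (returned as a canonical aligned raster) or an (n, 2)
    float array of points (returned transformed).
    """
    coords, is_raster = _mask_coords(body_mask)
    if len(coords) < 2 or np.allclose(coords, coords[0]):
        raise DegenerateMaskError("mask needs >= 2 distinct pixel positions")
    mean = coords.mean(axis=0)
    centred = coords - mean
    cov = centred.T @ centred / len(centred)
    evals, evecs = np.linalg.eigh(cov)
    major = evecs[:, int(np.argmax(evals))]
    angle = math.atan2(major[1], major[0])
    rotation = -angle
    R = np.array([[math.cos(rotation), -math.sin(rotation)],
                  [math.sin(rotation), math.cos(rotation)]])
    rotated = centred @ R.T
    # orientation sign: negative third central moment along the major axis
    if np.mean(rotated[:, 0] ** 3) > 0:
        rotation += math.pi
        R = -R
        rotated = -rotated
    extent = rotated[:, 0].max() - rotated[:, 0].min()
    if extent <= 0:
        raise DegenerateMaskError("mask has zero extent along major axis")
    offset = np.array([rotated[:, 0].min(), 0.0])
    rotation_deg = math.degrees(
        (rotation + math.pi) % (2 * math.pi) - math.pi)
    info = AlignmentInfo(rotation_deg=rotation_deg, mean=mean,
                         offset=offset, length_scale=float(extent))
    aligned_spots = SpotSet(info.apply(spots.xy),
                            spots.sizes / extent**2 if len(spots) else
                            spots.sizes,
                            frame=spots.frame, normalized=True,
                            length_scale=float(extent))
    if is_raster:
        aligned_mask = rasterize_aligned_mask(body_mask, info)
    else:
        aligned_mask = info.apply(coords)
    return aligned_spots, aligned_mask, info
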