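"""Spot constellations: the point patterns that identify individuals.

A constellation is an ordered set of spots, each with a position and a size
(area in pixels before normalization).  Raw constellations live in image
pixel coordinates (x right, y down, 0-based pixel centres); normalized
constellations are expressed in fish-length units so that x spans roughly
[0, 1] along the body axis.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np


@dataclass(frozen=True)
class Spot:
    """A single spot: centre position and area."""

    x: float
    y: float
    size: float

    def __post_init__(self):
        if self.size <= 0:
            raise ValueError(f"spot size must be positive, got {self.size}")


@dataclass
class SpotSet:
    """An ordered collection of spots with its coordinate-frame state.

    Parameters
    ----------
    xy : (n, 2) array of spot centres.
    sizes : (n,) array of spot areas (px^2 raw; scaled units once normalized).
    frame : (width, height) of the source frame, if known.
    normalized : True once coordinates are in fish-length units.
    length_scale : pixels per fish-length unit (set by normalization).
    """

    xy: np.ndarray
    sizes: np.ndarray
    frame: tuple[float, float] | None = None
    normalized: bool = False
    length_scale: float | None = None

    def __post_init__(self):
        self.xy = np.asarray(self.xy, dtype=float).reshape(-1, 2)
        self.sizes = np.asarray(self.sizes, dtype=float).reshape(-1)
        if len(self.xy) != len(self.sizes):
            raise ValueError("xy and sizes must have the same length")
        if len(self.sizes) and np.any(self.sizes <= 0):
            raise ValueError("all spot sizes must be positive")

    def __len__(self) -> int:
        return len(self.xy)

    def __iter__(self):
        for (x, y), s in zip(self.xy, self.sizes):
            yield Spot(float(x), float(y), float(s))

    @classmethod
    def empty(cls, frame=None, normalized=False) -> "SpotSet":
        return cls(np.empty((0, 2)), np.empty((0,)), frame=frame,
                   normalized=normalized)

    @classmethod
    def from_spots(cls, spots, frame=None, normalized=False) -> "SpotSet":
        spots = list(spots)
        xy = np.array([[s.x, s.y] for s in spots], dtype=float).reshape(-1, 2)
        sizes = np.array([s.size for s in spots], dtype=float)
        return cls(xy, sizes, frame=frame, normalized=normalized)

    def copy(self) -> "SpotSet":
        return SpotSet(self.xy.copy(), self.sizes.copy(), frame=self.frame,
                       normalized=self.normalized,
                       length_scale=self.length_scale)

    def select(self, indices) -> "SpotSet":
        """Sub-constellation at the given indices (order preserved)."""
        indices = np.asarray(indices, dtype=int)
        return SpotSet(self.xy[indices], self.sizes[indices], frame=self.frame,
                       normalized=self.normalized,
                       length_scale=self.length_scale)

    def scale_to_unit(self, length_scale: float) -> "SpotSet":
        """Divide coordinates by ``length_scale`` and flag as normalized."""
        if length_scale <= 0:
            raise ValueError("length_scale must be positive")
        return SpotSet(self.xy / length_scale,
                       self.sizes / length_scale**2,
                       frame=self.frame, normalized=True,
                       length_scale=length_scale)

    def allclose(self, other: "SpotSet", atol: float = 1e-9) -> bool:
        return (len(self) == len(other)
                and np.allclose(self.xy, other.xy, atol=atol)
                and np.allclose(self.sizes, other.sizes, atol=atol))


@dataclass
class Correspondence:
    """An injective mapping between spot indices of two constellations."""

    pairs: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self):
        a_side = [a for a, _ in self.pairs]
        b_side = [b for _, b in self.pairs]
        if len(set(a_side)) != len(a_side) or len(set(b_side)) != len(b_side):
            raise ValueError("correspondence must be injective on both sides")

    def __len__(self) -> int:
        return len(self.pairs)

    def __iter__(self):
        return iter(self.pairs)

    def as_dict(self) -> dict[int, int]:
        return dict(self.pairs)

    def inverse(self) -> "Correspondence":
        return Correspondence([(b, a) for a, b in self.pairs])

    @classmethod
    def identity(cls, n: int) -> "Correspondence":
        return cls([(i, i) for i in range(n)])
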