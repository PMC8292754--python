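"""Capture-history containers shared by the simulator and the CJS model."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ValidationError


@dataclass(frozen=True)
class CaptureRecord:
    """One capture event: who it really was, when, and what id was read."""

    true_id: str
    occasion: int
    observed_id: str


class CaptureHistoryMatrix:
    """n x T binary capture matrix with one row per individual.

    Invariant: every row contains at least one capture (rows of all zeros
    correspond to individuals that were never part of the study).
    """

    def __init__(self, y, ids=None):
        y = np.asarray(y, dtype=np.int8)
        if y.ndim != 2:
            raise ValidationError("capture histories must be a 2-D matrix")
        if not np.isin(y, (0, 1)).all():
            raise ValidationError("capture histories must be binary")
        if ids is None:
            ids = [f"ind{i:04d}" for i in range(y.shape[0])]
        ids = [str(i) for i in ids]
        if len(ids) != y.shape[0]:
            raise ValidationError("one id per row required")
        zero_rows = np.nonzero(~y.any(axis=1))[0]
        if len(zero_rows):
            raise ValidationError(
                f"row '{ids[zero_rows[0]]}' has no captures")
        self.y = y
        self.ids = ids

    @property
    def n(self) -> int:
        return self.y.shape[0]

    @property
    def n_occasions(self) -> int:
        return self.y.shape[1]

    @property
    def first_capture(self) -> np.ndarray:
        """Index of the first occasion with a 1, per row."""
        return self.y.argmax(axis=1)

    def __eq__(self, other) -> bool:
        if not isinstance(other, CaptureHistoryMatrix):
            return NotImplemented
        return self.y.shape == other.y.shape and (self.y == other.y).all()

    def __repr__(self) -> str:
        return (f"CaptureHistoryMatrix(n={self.n}, "
                f"T={self.n_occasions})")

    def canonical_rows(self) -> np.ndarray:
        """Rows sorted lexicographically (id-independent comparison)."""
        order = np.lexsort(self.y.T[::-1])
        return self.y[order]

    def equivalent(self, other: "CaptureHistoryMatrix") -> bool:
        """True when both matrices contain the same multiset of histories."""
        return (self.y.shape == other.y.shape
                and (self.canonical_rows() == other.canonical_rows()).all())
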