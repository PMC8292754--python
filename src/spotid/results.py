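"""Match results shared by both constellation matchers."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

from .spots import Correspondence


@dataclass
class MatchResult:
    """Outcome of comparing two constellations.

    ``score`` is the matcher-specific match strength (None when the pair
    could not be scored at all); ``accepted`` is the matcher's own
    accept/reject decision.  ``transform`` (similarity transform) and
    ``mask_fscore`` are filled by the RANSAC matcher only.
    """

    correspondence: Correspondence
    score: float | None
    accepted: bool
    transform: Any | None = None
    mask_fscore: float | None = None
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.accepted and self.score is None:
            raise ValueError("an accepted result must carry a score")
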