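"""Database and decision layer: chronological matching and bookkeeping.

Records are grouped into collections by capture date; a query from
collection k is only ever compared against records of collections
1..k-1, mimicking field work where earlier photographs of an individual
always predate the current one.  Ranking, open-set thresholding, the
OR-ensemble of the two matchers, accuracy bookkeeping, and the merge of
fragmented capture histories via accepted match links all live here.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Callable

import numpy as np

from .errors import ChronologyViolationError, ConflictError
from .groth import GrothConfig, GrothMatcher
from .histories import CaptureHistoryMatrix
from .ransac import AAConfig, RansacMatcher
from .results import MatchResult
from .spots import SpotSet

__all__ = [
    "ConstellationRecord",
    "ConstellationDatabase",
    "RankedMatches",
    "EvaluationCounts",
    "GrothRanker",
    "RansacRanker",
    "rank_matches",
    "decide_open_set",
    "ensemble_decision",
    "evaluate_open_set",
    "evaluate_closed_set",
    "correct_capture_histories",
]


@dataclass
class ConstellationRecord:
    """One photographed capture: normalized spots + aligned mask + metadata."""

    record_id: str
    date: Any                      # any totally ordered value (int occasion ok)
    spots: SpotSet
    mask: np.ndarray | None = None
    observed_tag: str | None = None
    fork_length: float | None = None
    true_id: str | None = None     # hidden ground truth in synthetic studies

    def __post_init__(self):
        if self.date is None:
            raise ValueError("record date is required")
        if not self.spots.normalized:
            raise ValueError("record spots must be normalized")


class ConstellationDatabase:
    """Chronologically ordered collections of constellation records."""

    def __init__(self):
        self._collections: list[tuple[Any, list[ConstellationRecord]]] = []

    @property
    def dates(self) -> list:
        return [d for d, _ in self._collections]

    def __len__(self) -> int:
        return sum(len(recs) for _, recs in self._collections)

    def add_collection(self, records, date) -> "ConstellationDatabase":
        if self._collections and not self._collections[-1][0] < date:
            raise ChronologyViolationError(
                f"collection date {date!r} not after {self._collections[-1][0]!r}")
        self._collections.append((date, list(records)))
        return self

    def records_before(self, date) -> list[ConstellationRecord]:
        """All records from collections strictly earlier than ``date``."""
        out = []
        for d, recs in self._collections:
            if d < date:
                out.extend(recs)
        return out

    def all_records(self) -> list[ConstellationRecord]:
        return [r for _, recs in self._collections for r in recs]


@dataclass
class RankedMatches:
    """Descending (record id, score) list; unscorable records rank last."""

    ranked: list[tuple[str, float]] = field(default_factory=list)
    unscored: list[str] = field(default_factory=list)
    results: dict[str, MatchResult] = field(default_factory=dict)

    def top(self) -> tuple[str, float] | None:
        return self.ranked[0] if self.ranked else None

    def rank_of(self, record_id: str) -> int | None:
        """1-based rank of a record; None when it received no score."""
        for i, (rid, _) in enumerate(self.ranked, start=1):
            if rid == record_id:
                return i
        return None

    def ids_in_order(self) -> list[str]:
        return [rid for rid, _ in self.ranked] + list(self.unscored)


class GrothRanker:
    """Triangle-voting matcher with per-record preparation caching."""

    def __init__(self, cfg: GrothConfig | None = None):
        self.cfg = cfg or GrothConfig()
        self.matcher = GrothMatcher(self.cfg)
        self._cache: dict[int, Any] = {}

    @property
    def threshold(self) -> float:
        return self.cfg.score_threshold

    def _prepared(self, record: ConstellationRecord):
        key = id(record)
        if key not in self._cache:
            self._cache[key] = self.matcher.prepare(record.spots)
        return self._cache[key]

    def score(self, query: ConstellationRecord,
              target: ConstellationRecord, seed: int = 0) -> MatchResult:
        return self.matcher.match_prepared(self._prepared(query),
                                           self._prepared(target))


class RansacRanker:
    """RANSAC matcher with per-record caching; seeded per comparison."""

    def __init__(self, cfg: AAConfig | None = None, threshold: float = 0.2):
        self.cfg = cfg or AAConfig()
        self.matcher = RansacMatcher(self.cfg)
        self.threshold = threshold
        self._cache: dict[int, Any] = {}

    def _prepared(self, record: ConstellationRecord):
        key = id(record)
        if key not in self._cache:
            self._cache[key] = self.matcher.prepare(record.spots)
        return self._cache[key]

    def score(self, query: ConstellationRecord,
              target: ConstellationRecord, seed: int = 0) -> MatchResult:
        return self.matcher.match_prepared(
            self._prepared(query), self._prepared(target),
            query.spots, target.spots, query.mask, target.mask, seed=seed)


def _comparison_seed(base_seed: int, qid: str, tid: str) -> int:
    import zlib
    h = zlib.crc32(f"{qid}|{tid}".encode())
    return int((base_seed * 1000003 + h) % (2**31))


def rank_matches(query: ConstellationRecord, db: ConstellationDatabase,
                 ranker, seed: int = 0) -> RankedMatches:
    """Score ``query`` against every record from earlier collections.

    Scored records are sorted by descending score (ties by record id);
    comparisons without a score are kept, ordered last.
    """
    out = RankedMatches()
    for rec in db.records_before(query.date):
        res = ranker.score(query, rec,
                           seed=_comparison_seed(seed, query.record_id,
                                                 rec.record_id))
        out.results[rec.record_id] = res
        if res.score is None:
            out.unscored.append(rec.record_id)
        else:
            out.ranked.append((rec.record_id, float(res.score)))
    out.ranked.sort(key=lambda t: (-t[1], t[0]))
    out.unscored.sort()
    return out


def decide_open_set(ranked: RankedMatches, threshold: float) -> str | None:
    """Accept the top-scored record when its score reaches ``threshold``."""
    top = ranked.top()
    if top is None or top[1] < threshold:
        return None
    return top[0]


def ensemble_decision(groth: str | None, aa: str | None) -> str | None:
    """OR-combination of the two matcher decisions.

    A match is declared when either matcher accepts; when both accept
    different records, the triangle-voting matcher wins (it has the
    better false-positive behaviour).
    """
    if groth is not None:
        return groth
    return aa


@dataclass
class EvaluationCounts:
    """Open-set confusion counts over a set of queries."""

    tp: int = 0
    fp: int = 0
    tn: int = 0
    fn: int = 0

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def open_set_accuracy(self) -> float:
        return (self.tp + self.tn) / self.total if self.total else 0.0


def evaluate_open_set(decisions: list[str | None],
                      truth: list[str | None]) -> EvaluationCounts:
    """Confusion counts; ``truth[i]`` is the correct prior record or None.

    A false positive is any accepted-but-wrong record, including accepting
    anything for a query that has no true prior match.
    """
    if len(decisions) != len(truth):
        raise ValueError("decisions and truth must have equal length")
    c = EvaluationCounts()
    for dec, tru in zip(decisions, truth):
        if tru is None:
            if dec is None:
                c.tn += 1
            else:
                c.fp += 1
        elif dec is None:
            c.fn += 1
        elif dec == tru:
            c.tp += 1
        else:
            c.fp += 1
    return c


def evaluate_closed_set(rankings: list[RankedMatches],
                        truth: list[str],
                        ks: tuple[int, ...] = (1, 2, 5)) -> dict[int, float]:
    """Rank-k accuracies over queries known to have a prior match."""
    if len(rankings) != len(truth):
        raise ValueError("rankings and truth must have equal length")
    if not rankings:
        return {k: 0.0 for k in ks}
    hits = {k: 0 for k in ks}
    for ranked, tru in zip(rankings, truth):
        r = ranked.rank_of(tru)
        for k in ks:
            if r is not None and r <= k:
                hits[k] += 1
    return {k: hits[k] / len(rankings) for k in ks}


class _UnionFind:
    def __init__(self):
        self.parent: dict[str, str] = {}

    def find(self, x: str) -> str:
        self.parent.setdefault(x, x)
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: str, b: str):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            # deterministic representative: lexicographically smallest
            lo, hi = sorted((ra, rb))
            self.parent[hi] = lo


def correct_capture_histories(
        links: list[tuple[ConstellationRecord, ConstellationRecord]],
        records: list[ConstellationRecord],
        occasions: list) -> CaptureHistoryMatrix:
    """Merge observed identities along accepted match links.

    ``links`` are (query record, matched earlier record) pairs; the
    observed tags of linked records are merged with union-find, and the
    capture history of each consolidated individual is the element-wise
    OR of its fragments.  Linking two records of the same collection is
    refused (an individual cannot be photographed twice as two different
    new fish on one occasion).
    """
    occ_index = {d: i for i, d in enumerate(occasions)}
    uf = _UnionFind()
    for rec in records:
        uf.find(rec.observed_tag or rec.record_id)
    for query, target in links:
        if query.date == target.date:
            raise ConflictError(
                f"link joins records {query.record_id} and "
                f"{target.record_id} of the same collection")
        uf.union(query.observed_tag or query.record_id,
                 target.observed_tag or target.record_id)
    rows: dict[str, np.ndarray] = {}
    for rec in records:
        root = uf.find(rec.observed_tag or rec.record_id)
        row = rows.setdefault(root, np.zeros(len(occasions), dtype=np.int8))
        row[occ_index[rec.date]] = 1
    ids = sorted(rows)
    return CaptureHistoryMatrix(np.stack([rows[i] for i in ids]), ids)
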