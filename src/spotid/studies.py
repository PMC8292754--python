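"""End-to-end synthetic studies: matching suites and tag-loss correction.

These orchestrators wire the generator, the matchers, the decision layer
and the survival model together at desk scale.  They define the standard
evaluation conditions used throughout the package:

* individuals carry 15-60 spots drawn inside a fish-shaped region of the
  normalized frame;
* a re-capture of the same individual is the original constellation under
  a similarity transform (rotation up to 10 degrees, growth scale up to
  1.3, a small translation), positional jitter of 0.005 fish lengths, and
  10% spot turnover in both directions;
* tag-loss studies additionally simulate survival/capture/tag-loss and
  correct the fragmented histories from accepted photograph matches.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cjs import PosteriorSummary, fit_cjs
from .groth import GrothConfig
from .histories import CaptureHistoryMatrix, CaptureRecord
from .pipeline import (ConstellationDatabase, ConstellationRecord,
                       GrothRanker, RansacRanker, _comparison_seed,
                       correct_capture_histories, decide_open_set,
                       evaluate_closed_set, evaluate_open_set, rank_matches)
from .ransac import AAConfig
from .spots import SpotSet
from .synthetic import (PerturbationSpec, PopulationSimSpec,
                        aligned_body_mask, generate_constellation,
                        inject_tag_loss, observed_history_matrix,
                        perturb_constellation, simulate_capture_histories)

__all__ = [
    "SyntheticIndividual",
    "make_individual",
    "recapture_spec",
    "run_closed_set_experiment",
    "run_open_set_experiment",
    "run_tag_loss_study",
]


@dataclass
class SyntheticIndividual:
    """A synthetic fish: its normalized constellation and aligned mask."""

    individual_id: str
    spots: SpotSet
    mask: np.ndarray
    half_depth: float
    taper: float


def make_individual(seed: int, individual_id: str | None = None,
                    n_spots_range: tuple[int, int] = (15, 60)
                    ) -> SyntheticIndividual:
    """Draw one individual: spot count, body shape and constellation.

    Body depth and tail taper vary per individual (real fish differ in
    condition and outline), which is what gives the mask-overlap gate its
    discriminative power between individuals.
    """
    rng = np.random.default_rng(seed)
    n_spots = int(rng.integers(n_spots_range[0], n_spots_range[1] + 1))
    half_depth = float(rng.uniform(0.13, 0.20))
    taper = float(rng.uniform(0.30, 0.60))
    spots = generate_constellation(
        n_spots, frame=(1.0, 2 * half_depth),
        seed=int(rng.integers(2**31)),
        radius_range=(0.012, 0.02),
        within_ellipse=((0.5, 0.0), (0.47, 0.88 * half_depth)),
        normalized=True)
    mask = aligned_body_mask(half_depth=half_depth, taper=taper)
    return SyntheticIndividual(individual_id or f"fish{seed}", spots, mask,
                               half_depth, taper)


def recapture_spec(rng: np.random.Generator,
                   rotation_max: float = 10.0,
                   scale_range: tuple[float, float] = (1.0, 1.3),
                   jitter_sd: float = 0.005,
                   drop_fraction: float = 0.10,
                   add_fraction: float = 0.10,
                   n_spots: int = 30) -> PerturbationSpec:
    """Perturbation drawn from the standard re-capture conditions."""
    return PerturbationSpec(
        rotation=float(rng.uniform(-rotation_max, rotation_max)),
        scale=float(rng.uniform(*scale_range)),
        translation=(float(rng.uniform(-0.02, 0.02)),
                     float(rng.uniform(-0.02, 0.02))),
        jitter_sd=jitter_sd,
        drop_fraction=drop_fraction,
        add_count=int(round(add_fraction * n_spots)),
        rng_seed=int(rng.integers(2**31)))


def _record(ind: SyntheticIndividual, spots: SpotSet, rec_id: str,
            date, observed_tag=None) -> ConstellationRecord:
    return ConstellationRecord(record_id=rec_id, date=date, spots=spots,
                               mask=ind.mask, observed_tag=observed_tag,
                               true_id=ind.individual_id)


def build_reidentification_suite(n_individuals: int = 40, seed: int = 0,
                                 **recapture_kwargs):
    """A database of first captures plus perturbed second captures.

    Returns (database, queries, truth) where ``truth`` maps each query to
    the record id of its first capture.
    """
    rng = np.random.default_rng(seed)
    individuals = [make_individual(int(rng.integers(2**31)), f"ind{i:03d}")
                   for i in range(n_individuals)]
    firsts = [_record(ind, ind.spots, f"rec0_{ind.individual_id}", 0)
              for ind in individuals]
    db = ConstellationDatabase().add_collection(firsts, 0)
    queries, truth = [], {}
    for ind, first in zip(individuals, firsts):
        spec = recapture_spec(rng, n_spots=len(ind.spots),
                              **recapture_kwargs)
        spots2, corr = perturb_constellation(ind.spots, spec)
        q = ConstellationRecord(
            record_id=f"rec1_{ind.individual_id}", date=1, spots=spots2,
            mask=_consistent_mask(ind, spots2, corr),
            true_id=ind.individual_id)
        queries.append(q)
        truth[q.record_id] = first.record_id
    return db, queries, truth


def _consistent_mask(ind: SyntheticIndividual, new_spots: SpotSet, corr):
    """The re-photographed body mask moves with its constellation."""
    from .ransac import estimate_similarity_transform, \
        transform_canonical_mask
    src = ind.spots.xy[[a for a, _ in corr]]
    dst = new_spots.xy[[b for _, b in corr]]
    if len(src) < 3:
        return ind.mask
    return transform_canonical_mask(
        ind.mask, estimate_similarity_transform(src, dst))


def run_closed_set_experiment(ranker, n_individuals: int = 40,
                              seed: int = 0, **recapture_kwargs):
    """Rank-1/2/5 accuracy of a matcher on the re-identification suite."""
    db, queries, truth = build_reidentification_suite(
        n_individuals, seed, **recapture_kwargs)
    rankings = [rank_matches(q, db, ranker, seed=seed) for q in queries]
    accuracies = evaluate_closed_set(
        rankings, [truth[q.record_id] for q in queries])
    return accuracies, rankings, truth


def run_open_set_experiment(ranker, threshold: float,
                            n_individuals: int = 40,
                            n_novel: int = 20, seed: int = 0,
                            **recapture_kwargs):
    """Open-set decisions for novel individuals against a known database."""
    db, _, _ = build_reidentification_suite(n_individuals, seed,
                                            **recapture_kwargs)
    rng = np.random.default_rng(seed + 987654)
    decisions = []
    for j in range(n_novel):
        ind = make_individual(int(rng.integers(2**31)), f"novel{j:03d}")
        q = _record(ind, ind.spots, f"novel_{j:03d}", 1)
        ranked = rank_matches(q, db, ranker, seed=seed)
        decisions.append(decide_open_set(ranked, threshold))
    counts = evaluate_open_set(decisions, [None] * n_novel)
    return counts, decisions


@dataclass
class TagLossStudyResult:
    truth: CaptureHistoryMatrix
    fragmented: CaptureHistoryMatrix
    corrected: CaptureHistoryMatrix
    n_queries: int
    n_links: int
    n_fragments: int
    fits: dict[str, PosteriorSummary] = field(default_factory=dict)


def run_tag_loss_study(pop: PopulationSimSpec | None = None,
                       seed: int = 0,
                       noiseless: bool = True,
                       n_spots_range: tuple[int, int] = (18, 36),
                       ranker=None,
                       fit_survival: bool = False,
                       n_mcmc: int = 8000) -> TagLossStudyResult:
    """Full tag-loss correction study on one simulated population.

    Simulates capture histories with tag loss, attaches a constellation to
    every capture event (noiseless: the individual's constellation itself;
    noisy: a mild per-event perturbation), matches each first appearance
    of an observed tag against the most recent prior record of every known
    tag, merges accepted links, and optionally fits the CJS model to the
    truth, the fragmented and the corrected histories.
    """
    pop = pop or PopulationSimSpec()
    rng = np.random.default_rng(seed)
    truth_matrix = simulate_capture_histories(pop)
    T = pop.n_occasions

    # capture events with true ids, then tag loss
    events = [CaptureRecord(true_id=truth_matrix.ids[i], occasion=t,
                            observed_id=truth_matrix.ids[i])
              for i in range(truth_matrix.n)
              for t in range(T) if truth_matrix.y[i, t]]
    observed = inject_tag_loss(events, pop.tag_loss_rate,
                               seed=int(rng.integers(2**31)))
    fragmented = observed_history_matrix(observed, T)
    n_fragments = fragmented.n - truth_matrix.n

    individuals = {tid: make_individual(int(rng.integers(2**31)), tid,
                                        n_spots_range=n_spots_range)
                   for tid in truth_matrix.ids}

    records: list[ConstellationRecord] = []
    for k, ev in enumerate(observed):
        ind = individuals[ev.true_id]
        if noiseless:
            spots = ind.spots
            mask = ind.mask
        else:
            spec = recapture_spec(rng, rotation_max=5.0,
                                  scale_range=(1.0, 1.15),
                                  jitter_sd=0.003, drop_fraction=0.05,
                                  add_fraction=0.05,
                                  n_spots=len(ind.spots))
            spots, corr = perturb_constellation(ind.spots, spec)
            mask = _consistent_mask(ind, spots, corr)
        records.append(ConstellationRecord(
            record_id=f"photo{k:05d}", date=ev.occasion, spots=spots,
            mask=mask, observed_tag=ev.observed_id,
            true_id=ev.true_id))

    ranker = ranker or GrothRanker(GrothConfig())
    links = []
    n_queries = 0
    latest_by_tag: dict[str, ConstellationRecord] = {}
    for t in range(T):
        todays = [r for r in records if r.date == t]
        # queries: tags never seen before (untagged fish at the bench)
        for r in todays:
            if r.observed_tag in latest_by_tag:
                continue
            candidates = list(latest_by_tag.values())
            if candidates:
                n_queries += 1
                scored = []
                for c in candidates:
                    res = ranker.score(
                        r, c, seed=_comparison_seed(seed, r.record_id,
                                                    c.record_id))
                    if res.score is not None:
                        scored.append((res.score, c))
                scored.sort(key=lambda t_: (-t_[0], t_[1].record_id))
                if scored and scored[0][0] >= ranker.threshold:
                    links.append((r, scored[0][1]))
        for r in todays:
            latest_by_tag[r.observed_tag] = r

    corrected = correct_capture_histories(links, records, list(range(T)))

    result = TagLossStudyResult(truth=truth_matrix, fragmented=fragmented,
                                corrected=corrected, n_queries=n_queries,
                                n_links=len(links),
                                n_fragments=n_fragments)
    if fit_survival:
        for name, mat in (("truth", truth_matrix),
                          ("fragmented", fragmented),
                          ("corrected", corrected)):
            result.fits[name] = fit_cjs(mat, n_samples=n_mcmc,
                                        seed=int(seed) + 17)
    return result
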