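"""Match a spot constellation against a perturbed re-capture of itself.

Generates one individual's constellation, simulates a second capture
(rotation, growth, jitter, spot turnover), and runs both matchers: the
triangle-voting matcher and the RANSAC matcher with the mask-overlap gate.
"""

from spotid import PerturbationSpec, groth_match, ransac_match_aa
from spotid.studies import make_individual
from spotid.synthetic import perturb_constellation

ind = make_individual(seed=11)
print(f"individual with {len(ind.spots)} spots")

spec = PerturbationSpec(rotation=7.0, scale=1.12, translation=(0.01, -0.01),
                        jitter_sd=0.005, drop_fraction=0.1, add_count=3,
                        rng_seed=3)
recapture, truth = perturb_constellation(ind.spots, spec)
print(f"re-capture: {len(truth)} spots survived, {len(recapture)} total")

g = groth_match(ind.spots, recapture)
correct = len(set(g.correspondence.pairs) & set(truth.pairs))
print(f"voting matcher: score={g.score:.1f} accepted={g.accepted} "
      f"({correct}/{len(truth)} true pairs recovered)")
print("  a score above the acceptance threshold 6.5 declares a re-capture")

r = ransac_match_aa(ind.spots, ind.mask, recapture, ind.mask, seed=1)
print(f"RANSAC matcher: score={r.score:.2f} mask overlap={r.mask_fscore:.2f}")
print(f"  recovered transform: rotation={r.transform.rotation:.2f} deg "
      f"(true 7.00), scale={r.transform.scale:.3f} (true 1.120)")
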