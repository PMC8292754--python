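"""Tag loss fragments capture histories and biases survival downward.

Simulates a marked population with 7% tag loss per recapture, corrects the
fragmented histories by photo re-identification, and fits the Bayesian
Cormack-Jolly-Seber model to the true, fragmented and corrected histories.
"""

from spotid.studies import run_tag_loss_study
from spotid.synthetic import PopulationSimSpec

pop = PopulationSimSpec(n_individuals=80, n_occasions=10,
                        phi=0.78, p=0.53, tag_loss_rate=0.07, rng_seed=4)
res = run_tag_loss_study(pop, seed=4, noiseless=True, fit_survival=True,
                         n_mcmc=4000)

print(f"{res.truth.n} individuals captured; tag loss created "
      f"{res.n_fragments} spurious identities")
print(f"photo matching merged {res.n_links} fragments "
      f"({res.n_queries} queries)")
print(f"corrected histories identical to the truth: "
      f"{res.corrected.equivalent(res.truth)}")
for name in ("truth", "fragmented", "corrected"):
    fit = res.fits[name]
    lo, hi = fit.phi_hpd
    print(f"  {name:10s} phi = {fit.phi_mean:.3f} (95% HPD {lo:.3f}-{hi:.3f})")
print("Fragmentation makes individuals 'disappear', so the fragmented-data")
print("survival estimate sits below the corrected one (true phi = 0.78).")
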