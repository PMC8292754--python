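import warnings

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

# deterministic, CI-friendly hypothesis profile
settings.register_profile(
    "default", deadline=None, derandomize=True, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("default")

warnings.filterwarnings("ignore", category=FutureWarning)


@pytest.fixture(scope="session")
def default_render():
    """One default synthetic photograph with its ground-truth masks."""
    from spotid.synthetic import SyntheticFishSpec, render_fish_image
    return render_fish_image(SyntheticFishSpec(rng_seed=0))


@pytest.fixture(scope="session")
def small_individuals():
    """A handful of synthetic individuals for matcher tests."""
    from spotid.studies import make_individual
    return [make_individual(seed) for seed in range(1, 7)]


def standard_recapture(spots, seed, rotation=None, scale=1.1):
    """A re-capture perturbation drawn from the standard study conditions."""
    import numpy as np
    from spotid.synthetic import PerturbationSpec, perturb_constellation
    rng = np.random.default_rng(seed)
    spec = PerturbationSpec(
        rotation=float(rng.uniform(-10, 10)) if rotation is None else rotation,
        scale=scale,
        translation=(float(rng.uniform(-0.02, 0.02)),
                     float(rng.uniform(-0.02, 0.02))),
        jitter_sd=0.005, drop_fraction=0.1,
        add_count=max(1, round(0.1 * len(spots))),
        rng_seed=seed + 500)
    return perturb_constellation(spots, spec)
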