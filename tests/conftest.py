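import numpy as np
import pytest

from egmdur import CohortSpec, generate_cohort

COHORT_SEED = 7  # fixed seed defining the synthetic study conditions


@pytest.fixture(scope="session")
def cohort16():
    """The full-scale synthetic study: 16 patients x 2000 points, seed 7."""
    spec = CohortSpec(seed=COHORT_SEED)
    maps, truths = generate_cohort(spec, return_truth=True)
    return maps, truths


@pytest.fixture(scope="session")
def small_cohort():
    """A light cohort for functional (non-statistical) checks."""
    spec = CohortSpec(n_patients=2, points_per_map=300, seed=11)
    maps, truths = generate_cohort(spec, return_truth=True)
    return maps, truths


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
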