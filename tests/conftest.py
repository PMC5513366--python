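import logging

import numpy as np
import pytest
from hypothesis import settings as hyp_settings

hyp_settings.register_profile("repro", derandomize=True, deadline=None)
hyp_settings.load_profile("repro")

from psajoint import (
    DesignSpec,
    PopulationParameters,
    simulate_cohort,
    transform_to_natural,
)

logging.getLogger("psajoint").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def pop():
    """Reference population parameters (current-PSA link)."""
    return PopulationParameters()


@pytest.fixture(scope="session")
def pop_nolink(pop):
    """Weibull-only survival: link switched off."""
    return pop.with_link("none", 0.0)


@pytest.fixture(scope="session")
def psi_ref(pop):
    """Typical-subject kinetics (random effects at zero)."""
    return transform_to_natural(pop, np.zeros(4))


@pytest.fixture(scope="session")
def small_cohort(pop):
    """30-subject simulated cohort shared across tests."""
    return simulate_cohort(pop, DesignSpec(n_subjects=30, seed=424242))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20170717)
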