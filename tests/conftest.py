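"""Shared fixtures: the default synthetic study system and one full MCMC fit.

The expensive recovery fit (3 chains x 20,000 iterations on the default
20x20 system) is session-scoped so the acceptance checks that consume it
run it exactly once.
"""

import warnings

import numpy as np
import pytest

warnings.filterwarnings("ignore", category=FutureWarning, module="arviz")

from envenom.model import fit_mcmc
from envenom.synth import make_default_truth, simulate_incidence

RECOVERY_SEED = 1
RECOVERY_OBS_SEED = 2
RECOVERY_MCMC_SEED = 3


@pytest.fixture(scope="session")
def truth():
    """Default synthetic study system (20x20, 1 km cells, 2008-2050)."""
    return make_default_truth(seed=RECOVERY_SEED)


@pytest.fixture(scope="session")
def observed(truth):
    """One simulated envenoming survey at the 2010 baseline."""
    return simulate_incidence(truth, 2010, seed=RECOVERY_OBS_SEED)


@pytest.fixture(scope="session")
def recovery_fit(truth, observed):
    """The full parameter-recovery MCMC fit (3 x 20k iterations)."""
    return fit_mcmc(
        observed,
        truth.species,
        truth.landcover,
        truth.h2010_layer(),
        n_chains=3,
        n_iter=20000,
        seed=RECOVERY_MCMC_SEED,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(20240807)
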