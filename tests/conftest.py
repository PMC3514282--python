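import numpy as np
import pytest

from ivf_jointfx.cohort import AgeClass, AttemptRecord, Center, Cohort, CoupleHistory
from ivf_jointfx.mcmc import MCMCConfig, fit_mcmc
from ivf_jointfx.simulate import GeneratorConfig, default_generating_params, simulate_cohort


def make_history(couple_id, center, age, pattern):
    """Build a history from (n_continue, outcome) with outcome in
    {'success', 'disc', 'censored'}."""
    n_cont, outcome = pattern
    attempts = [AttemptRecord(j, 0, 0) for j in range(1, n_cont + 1)]
    j = n_cont + 1
    if outcome == "success":
        attempts.append(AttemptRecord(j, 1, None))
    elif outcome == "disc":
        attempts.append(AttemptRecord(j, 0, 1))
    else:
        assert j == 4
        attempts.append(AttemptRecord(j, 0, None))
    return CoupleHistory(couple_id, center, age, tuple(attempts))


@pytest.fixture(scope="session")
def generating_params():
    return default_generating_params()


@pytest.fixture(scope="session")
def small_cohort():
    """A 300-couple synthetic cohort at the default generating values."""
    return simulate_cohort(GeneratorConfig(n_couples=300, seed=42))


@pytest.fixture(scope="session")
def recovery_fit(generating_params):
    """The standard parameter-recovery run: a 3,002-couple cohort simulated
    at the default generating values, fitted with the desk protocol
    (2 chains x 6,000 iterations, burn-in 1,000, thin 5).  Shared across
    the recovery and diagnostics checks because it is the most expensive
    fit in the battery."""
    cohort = simulate_cohort(GeneratorConfig(n_couples=3002, seed=0))
    post = fit_mcmc(cohort, config=MCMCConfig(seed=0))
    return generating_params, cohort, post
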