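import numpy as np
import pytest

from simgrowth import (
    GrowthParams,
    OutcomeParams,
    draw_age_schedule,
    simulate_trajectories,
)

BASELINE_GROWTH = GrowthParams()
BASELINE_OUTCOME = OutcomeParams()


@pytest.fixture(scope="session")
def schedule_small():
    """Fixed jittered age schedule, J=200."""
    return draw_age_schedule(n_individuals=200, seed=101)


@pytest.fixture(scope="session")
def data_small(schedule_small):
    """One baseline dataset at J=200."""
    return simulate_trajectories(
        schedule_small, BASELINE_GROWTH, BASELINE_OUTCOME, seed=202
    )


@pytest.fixture(scope="session")
def schedule_large():
    """Fixed jittered age schedule at the study size, J=1000."""
    return draw_age_schedule(n_individuals=1000, seed=303)


@pytest.fixture(scope="session")
def data_large(schedule_large):
    return simulate_trajectories(
        schedule_large, BASELINE_GROWTH, BASELINE_OUTCOME, seed=404
    )


@pytest.fixture(scope="session")
def noiseless_data():
    """sigma_eh = 0, outcome noiseless and unlinked: heights lie exactly
    on each individual's latent line."""
    sched = draw_age_schedule(n_individuals=120, seed=55)
    growth = GrowthParams(sigma_eh=0.0)
    outcome = OutcomeParams(alpha3=0.0, alpha4=0.0, sigma_ebp=0.0)
    return simulate_trajectories(sched, growth, outcome, seed=56)
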