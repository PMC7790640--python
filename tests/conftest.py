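import numpy as np
import pytest

from salipm import (
    SimulationTruth,
    SurveyDesign,
    posterior_mean_params,
    simulate_population,
)


@pytest.fixture(scope="session")
def table1():
    """Published posterior means of the joint model."""
    return posterior_mean_params()


@pytest.fixture(scope="session")
def small_design():
    """A trimmed 3-site two-season layout for fast tests."""
    occ = {
        "site1": [0.0, 1.0, 2.5, 3.5, 12.0, 13.0, 14.0],
        "site2": [0.0, 1.0, 3.5, 4.5, 12.0, 13.0, 14.0],
        "site3": [0.0, 1.0, 3.5, 4.5, 12.0, 13.0, 14.0, 15.0],
    }
    return SurveyDesign(
        occasion_times=occ,
        season_break={s: 4 for s in occ},
        n_initial={s: 80 for s in occ},
    )


@pytest.fixture(scope="session")
def small_data(small_design):
    """Simulated capture histories at the published parameter values."""
    return simulate_population(SimulationTruth(seed=11), small_design)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
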