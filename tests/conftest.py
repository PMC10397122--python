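import warnings

import pytest

from batnight import gam
from batnight import synthetic as syn


@pytest.fixture(scope="session")
def small_scenario():
    """A reduced campaign (4 platforms, 3 stations, one season) for fast tests."""
    cfg = syn.ScenarioConfig(n_locations=4, n_stations=4, years=(2019,), seed=11)
    return syn.simulate_scenario(cfg)


@pytest.fixture(scope="session")
def default_scenario():
    """One full-size campaign (13 platforms, 8 stations, three seasons)."""
    return syn.simulate_scenario(syn.ScenarioConfig(seed=1))


@pytest.fixture(scope="session")
def fitted_default(default_scenario):
    """The default scenario fitted with selected smoothing parameters."""
    design = gam.assemble_design(default_scenario.night_table)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        lam = gam.select_lambda(design)
        model = gam.fit_pirls(design, lam)
    return default_scenario, model
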