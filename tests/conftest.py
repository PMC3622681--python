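"""Shared fixtures: task geometry, plant, and a simulated training session.

The expensive objects (an 89-trial manual session and the encoding
models fitted to it) are session-scoped so the suite builds them once.
"""

from __future__ import annotations

import numpy as np
import pytest

from ofcbmi import (
    PlantParams,
    discretize_plant,
    fit_kinematic_model,
    fit_target_model,
    make_center_out_config,
    make_population,
    run_session,
)
from ofcbmi.simulate import default_cost_template


@pytest.fixture(scope="session")
def config():
    return make_center_out_config()


@pytest.fixture(scope="session")
def plant(config):
    return discretize_plant(PlantParams(dt=config.bin_s))


@pytest.fixture(scope="session")
def cost_template():
    return default_cost_template()


@pytest.fixture(scope="session")
def population(config):
    return make_population(seed=3, config=config)


@pytest.fixture(scope="session")
def manual_session(population, config, plant, cost_template):
    records, summary = run_session(
        n_trials=89, mode="manual", pop=population, config=config,
        sys=plant, cost_template=cost_template, seed=11,
    )
    return records, summary


@pytest.fixture(scope="session")
def fitted_models(manual_session, config):
    records, _ = manual_session
    target_model = fit_target_model(records, config)
    kin_model, stats = fit_kinematic_model(records, config.bin_s)
    return target_model, kin_model, stats
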