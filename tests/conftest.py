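"""Shared fixtures: expensive steady states are computed once per session."""

import numpy as np
import pytest

import thermoclo as tc


@pytest.fixture(scope="session")
def registry():
    return tc.load_default_body()


@pytest.fixture(scope="session")
def steady_A(registry):
    scen = tc.load_reference_scenario("A", registry=registry)
    return scen, tc.steady_state(scen)


@pytest.fixture(scope="session")
def steady_D(registry):
    scen = tc.load_reference_scenario("D", registry=registry)
    return scen, tc.steady_state(scen)


@pytest.fixture(scope="session")
def steady_neutral(registry):
    scen = tc.thermal_neutrality_scenario(registry=registry)
    return scen, tc.steady_state(scen)


@pytest.fixture(scope="session")
def onset_sweep(registry):
    scen = tc.load_reference_scenario("A", registry=registry)
    grid = np.linspace(0.005, 0.0195, 8)
    return tc.convection_onset_sweep(scen, grid)


@pytest.fixture(scope="session")
def paper_bundle(registry):
    return tc.run_paper_experiment(registry=registry)
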