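import pytest

from hemodelay import ModelParameters, make_scenario, run_scenario


@pytest.fixture(scope="session")
def table_params() -> ModelParameters:
    """Baseline parameter set (no deprivation, no cytokine)."""
    return ModelParameters()


@pytest.fixture(scope="session")
def baseline_traj():
    """Long baseline run from (P, N, A) = (1000, 10000, 0)."""
    return run_scenario(make_scenario("baseline", t_end=400.0))


@pytest.fixture(scope="session")
def deprivation_traj():
    """Deprivation run under the frozen-rate reading, matched settings."""
    return run_scenario(make_scenario("deprivation", t_end=400.0))


@pytest.fixture(scope="session")
def cytokine_traj():
    """Deprivation + cytokine run, matched settings."""
    return run_scenario(make_scenario("deprivation_cytokine", t_end=400.0))
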