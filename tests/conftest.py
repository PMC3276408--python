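import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from hwpcarbon import (  # noqa: E402
    default_parameter_fixture,
    generate_harvest,
    run_production,
    scenario_preset,
)


@pytest.fixture(scope="session")
def params():
    return default_parameter_fixture()


@pytest.fixture(scope="session")
def figure3_records(params):
    return generate_harvest(scenario_preset("figure3_like", seed=7), params)


@pytest.fixture(scope="session")
def figure3_run(figure3_records, params):
    """One deterministic full-chain run shared across tests."""
    return run_production(figure3_records, params, end_year=2010)
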