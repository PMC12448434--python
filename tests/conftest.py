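import pytest
from hypothesis import HealthCheck, settings

from mnhcea import AerialLogisticsCEA, ParameterSet

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def params() -> ParameterSet:
    return ParameterSet.defaults()


@pytest.fixture(scope="session")
def model(params) -> AerialLogisticsCEA:
    return AerialLogisticsCEA(params)


@pytest.fixture(scope="session")
def base_results(model):
    return model.fit()
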