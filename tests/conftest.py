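import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from metaripe import SigmoidParams, default_profiles, load_default_parameters


@pytest.fixture(scope="session")
def default_params():
    """Packaged cultivar-average parameters: cultivar -> {T -> SigmoidParams}."""
    return load_default_parameters()


@pytest.fixture(scope="session")
def miracle12(default_params):
    """Miracle at 12 degC: the canonical worked-example curve."""
    return default_params["Miracle"][12.0]


@pytest.fixture(scope="session")
def profiles():
    return default_profiles()
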