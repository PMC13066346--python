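import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from straincut import build_mini_lignin, build_precursor_demo


@pytest.fixture(scope="session")
def mini():
    """(model, medium, coupling spec) for the mini-lignin fixture."""
    return build_mini_lignin()


@pytest.fixture(scope="session")
def mini_model(mini):
    return mini[0]


@pytest.fixture(scope="session")
def mini_spec(mini):
    return mini[2]


@pytest.fixture(scope="session")
def precursor():
    return build_precursor_demo()
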