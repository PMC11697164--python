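import warnings

import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def no_warnings():
    """Context in which expected warnings are silenced."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        yield
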