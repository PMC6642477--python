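import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

from mlpacnv import default_panel  # noqa: E402


@pytest.fixture(scope="session")
def panel():
    return default_panel()
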