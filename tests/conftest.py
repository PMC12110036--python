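import pytest
from hypothesis import HealthCheck, settings

from lampsim import TargetLayout

settings.register_profile(
    "default",
    max_examples=50,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def classic_layout() -> TargetLayout:
    return TargetLayout.classic()


@pytest.fixture(scope="session")
def phn_layout() -> TargetLayout:
    return TargetLayout.phn()
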