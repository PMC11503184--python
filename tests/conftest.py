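import pytest
from hypothesis import HealthCheck, settings

from ps4lr import CaseControlCounts, TargetORPair

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def scenario1_counts():
    """10 carriers / 10 000 cases vs 2 / 10 000 controls: the borderline
    balanced scenario (observed OR 5.0, p just under 0.05)."""
    return CaseControlCounts(10, 10_000, 2, 10_000)


@pytest.fixture
def default_targets():
    return TargetORPair(5, 1)
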