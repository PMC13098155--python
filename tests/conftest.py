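import pytest
from hypothesis import HealthCheck, settings

from nodusym.simulate import GroundTruth

settings.register_profile(
    "default", deadline=None, derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("default")


@pytest.fixture(scope="session")
def gt():
    """Default ground truth (published cohort means, SE-derived CVs)."""
    return GroundTruth.default(seed=0)


@pytest.fixture(scope="session")
def gt0(gt):
    """Zero-noise variant: every CV set to 0, means unchanged."""
    return gt.zero_noise()
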