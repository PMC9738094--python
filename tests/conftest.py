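import pytest
from hypothesis import HealthCheck, settings

import brcaness as b

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def panel():
    return b.load_default_panel()


@pytest.fixture(scope="session")
def small_cohort():
    """A small planted-signal cohort shared across read-only tests."""
    design = b.default_design(seed=11, n_per_type=60, n_normals=8)
    bundle, truth = b.generate(design)
    return bundle, truth
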