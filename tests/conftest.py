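import pytest
from hypothesis import HealthCheck, settings

from abcost import bundled_dataset

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def thyroidectomy():
    return bundled_dataset("total_thyroidectomy")


@pytest.fixture(scope="session")
def hemithyroidectomy():
    return bundled_dataset("hemithyroidectomy")


@pytest.fixture(scope="session")
def ablation():
    return bundled_dataset("thermal_ablation")
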