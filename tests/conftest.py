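import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import vitdcea as v

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def cfg():
    return v.default_config()


@pytest.fixture(scope="session")
def bundles(cfg):
    return {label: v.build_bundle(cfg, label) for label in ("light", "medium", "dark")}


@pytest.fixture(scope="session")
def no_mortality_model():
    """Engine config with zero mortality (isolates utility arithmetic)."""
    return v.ModelConfig(life_table=np.zeros(101))
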