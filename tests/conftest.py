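import numpy as np
import pytest
from hypothesis import settings

from sixarm.agents import ModelParams
from sixarm.task import Schedule

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def tiny_schedule() -> Schedule:
    """A miniature schedule: short exploration plus two short contingencies."""
    return Schedule.default(
        contingency_order=("234", "123"),
        explore_sessions=2,
        rewards_per_explore_session=10,
        days_per_contingency=1,
        sessions_per_day=2,
    )


@pytest.fixture(scope="session")
def mid_params() -> ModelParams:
    return ModelParams(alpha=0.4, gamma=0.5, omega=0.005)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
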