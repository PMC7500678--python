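import hypothesis
import numpy as np
import pytest

from hermetia.profiles import builtin_profile
from hermetia.state import EnvironmentSchedule, EnvironmentState

hypothesis.settings.register_profile(
    "suite", derandomize=True, deadline=None, max_examples=50
)
hypothesis.settings.load_profile("suite")


@pytest.fixture(scope="session")
def profile_original():
    return builtin_profile("table3_original")


@pytest.fixture(scope="session")
def profile_recal():
    return builtin_profile("table3_recalibrated_D1D5")


@pytest.fixture(scope="session")
def optimal_env():
    """Near-optimal constant conditions: thermal-response peak temperature,
    saturating feed, plateau moisture, high airflow."""
    return EnvironmentState(T_med=31.0, B_feed=0.2, W_med_pct=0.72, A_air=3.0)


@pytest.fixture(scope="session")
def optimal_schedule(optimal_env):
    return EnvironmentSchedule.constant(optimal_env)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
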