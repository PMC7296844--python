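import numpy as np
import pytest

from rewardconn import rl, synth
from rewardconn.task import TaskConfig, generate_schedule


@pytest.fixture(scope="session")
def task_config():
    return TaskConfig()


@pytest.fixture(scope="session")
def compact_config():
    return TaskConfig.compact()


@pytest.fixture(scope="session")
def schedule(task_config):
    return generate_schedule(task_config, seed=123)


@pytest.fixture(scope="session")
def model3():
    return rl.MODELS[3]


@pytest.fixture(scope="session")
def params3(model3):
    return rl.RLParams.from_theta(
        np.array([rl.logit(0.4), rl.logit(0.2), np.log(3.0)]), model3
    )


@pytest.fixture(scope="session")
def session_trials(schedule, model3, params3, task_config):
    """One simulated 66-trial session (miss-free)."""
    return synth.simulate_agent(schedule, model3, params3, task_config, seed=7)


@pytest.fixture(scope="session")
def small_cohort():
    """A 12-subject model-3 cohort for fast hierarchical-fitting tests."""
    return synth.generate_cohort(12, model=3, seed=42)
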