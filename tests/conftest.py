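import numpy as np
import pytest

from dynaprl import models, task
from dynaprl.cohort import make_fixtures


@pytest.fixture(scope="session")
def fixtures():
    return make_fixtures()


@pytest.fixture(scope="session")
def task_config():
    return task.TaskConfig()


@pytest.fixture(scope="session")
def standard_trials(task_config):
    """A moderate standard-RL dataset reused by several read-only tests."""
    rng = np.random.default_rng(1234)
    params = models.StandardParams(alpha=0.35, beta=4.0)
    return models.simulate_agent("standard", params, task_config, 5, 300, rng)


def random_mini_session(rng, session_id="M0", max_trials=20):
    """A random small trial table exercising all strata (for oracle tests)."""
    import pandas as pd

    n = int(rng.integers(1, max_trials + 1))
    block_types = rng.choice(["HC", "LC", "NC"], size=n)
    better = np.where(
        block_types == "NC", "none", rng.choice(["A1", "A2"], size=n)
    )
    return pd.DataFrame(
        {
            "session_id": session_id,
            "trial_index": np.arange(1, n + 1),
            "block_id": np.cumsum(rng.random(n) < 0.1),
            "block_type": block_types,
            "block_trial_index": rng.integers(1, 25, size=n),
            "choice": rng.choice(["A1", "A2"], size=n),
            "outcome": rng.integers(0, 2, size=n),
            "reward_volume": 0.0,
            "better_action": better,
            "valid": rng.random(n) > 0.05,
        }
    )
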