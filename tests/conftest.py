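import numpy as np
import pytest

from navrl import compute_mb_values, default_task
from navrl.gridworld import GridSpec


@pytest.fixture(scope="session")
def task():
    return default_task()


@pytest.fixture(scope="session")
def grid(task):
    return task.grid


@pytest.fixture(scope="session")
def mb(task):
    """Precomputed model-based table shared across tests."""
    return compute_mb_values(task)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240101)
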