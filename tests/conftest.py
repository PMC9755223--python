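import warnings

import numpy as np
import pytest

from sleepreplay import (TrainingConfig, init_network)


@pytest.fixture(autouse=True)
def _quiet_expected_warnings():
    # individual tests re-enable warnings checks with pytest.warns where needed
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        yield


@pytest.fixture
def small_net():
    """A deterministic 4-6-3 wake network with non-trivial weights."""
    return init_network([4, 6, 3], TrainingConfig(init_range=0.5, seed=123))


@pytest.fixture(scope="session")
def fixture_experiment():
    """One full two-task fixture run shared by the slower analysis tests."""
    from sleepreplay import run_two_task_fixture_experiment

    return run_two_task_fixture_experiment(seed=0)
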