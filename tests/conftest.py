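import numpy as np
import pytest

from hjortheeg import TaskCode, default_config, generate_trial


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture(scope="session")
def config():
    return default_config(seed=11)


@pytest.fixture(scope="session")
def rest_and_crh_trials(config):
    """30 Rest + 30 CRH trials from the shipped defaults (fixed seed)."""
    trials = [generate_trial(config, TaskCode.REST, "S01", i) for i in range(30)]
    trials += [generate_trial(config, TaskCode.CRH, "S01", i) for i in range(30)]
    return trials
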