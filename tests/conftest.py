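import numpy as np
import pytest

from caldrift import SynthConfig, make_experiment, make_stimulus_set


@pytest.fixture(scope="session")
def stimulus_set():
    """The default 8 PT + 8 CxS stimulus set, built once per session."""
    return make_stimulus_set(seed=1)


@pytest.fixture(scope="session")
def small_experiment():
    """A small 2-day experiment with moderate drift, shared across tests."""
    cfg = SynthConfig(n_neurons=12, n_days=2, seed=7)
    stimuli = make_stimulus_set(seed=7)
    sessions, truth = make_experiment(cfg, stimuli)
    return cfg, stimuli, sessions, truth


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
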