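import numpy as np
import pytest

import rsvptriage as rt


@pytest.fixture(scope="session")
def small_to_config():
    """A short TO session: quick to simulate, still ~480 trials."""
    return rt.SimulationConfig(condition="TO", n_blocks=2, seed=7)


@pytest.fixture(scope="session")
def small_to_session(small_to_config):
    seq, eeg = rt.simulate_session(small_to_config)
    return small_to_config, seq, eeg


@pytest.fixture(scope="session")
def small_to_epochs(small_to_session):
    _, seq, eeg = small_to_session
    return rt.classification_epochs(eeg, seq)


@pytest.fixture(scope="session")
def tn_report():
    """Full nested-CV report with sweep on one default TN session."""
    cfg = rt.SimulationConfig(condition="TN", seed=1)
    seq, eeg = rt.simulate_session(cfg)
    epochs = rt.classification_epochs(eeg, seq)
    return rt.run_pipeline(epochs, "tn_tvbnt", sweep=True)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
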