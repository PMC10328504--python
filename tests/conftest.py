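import numpy as np
import pytest

import ctc_evoked as ce


@pytest.fixture(scope="session")
def quiet_session():
    """Deep-stimulation quiet-wakefulness session: 60 trials, EEG + spikes."""
    cfg = ce.default_config("deep", states=("quiet",), n_trials_per_state=60, seed=7)
    return ce.simulate_session(cfg)


@pytest.fixture(scope="session")
def three_state_session():
    """Deep stimulation, quiet + running + anesthetized, 25 trials each."""
    cfg = ce.default_config(
        "deep", states=("quiet", "running", "anesthetized"), n_trials_per_state=25, seed=3
    )
    return ce.simulate_session(cfg)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
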