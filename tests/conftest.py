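import numpy as np
import pytest

from nbgnet import synthetic as syn


@pytest.fixture(scope="session")
def small_transfer():
    """Ground-truth 6->3 transfer at 1 kHz."""
    return syn.default_transfer(n_fine=6, n_coarse=3, fs=1000.0, seed=7)


@pytest.fixture(scope="session")
def small_session(small_transfer):
    """A compact session for the analysis modules: 24 trials, 6->3 channels."""
    cfg = syn.SimConfig(n_fine=6, n_coarse=3, n_trials=24, trial_length=1.2, seed=42)
    return syn.simulate_session(cfg, small_transfer)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
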