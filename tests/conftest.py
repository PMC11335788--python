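import numpy as np
import pytest

import pupilkit as pk


@pytest.fixture(scope="session")
def step_trials_noiseless():
    """Ten forward-model trials with zero noise (shared across tests)."""
    truth = pk.SimulationTruth(noise_sd=0.0, seed=11)
    return truth, pk.simulate_trials(10, truth, seed=42)


@pytest.fixture(scope="session")
def step_trials_noisy():
    truth = pk.SimulationTruth(noise_sd=0.5, seed=11)
    return truth, pk.simulate_trials(10, truth, seed=42)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
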