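import numpy as np
import pytest

import musclemod as mm
from musclemod.datatypes import TrialSet


@pytest.fixture(scope="session")
def moderate_truth():
    return mm.make_subject_truth("moderate", seed=7)


@pytest.fixture(scope="session")
def moderate_trials(moderate_truth):
    return mm.simulate_trialset(moderate_truth)


@pytest.fixture(scope="session")
def noiseless_truth():
    return mm.make_subject_truth("moderate", seed=3, noise_sd=0.0)


@pytest.fixture(scope="session")
def noiseless_trials(noiseless_truth):
    return mm.simulate_trialset(noiseless_truth)


@pytest.fixture
def constant_trialset():
    """All 96 trials identical: task i has activation vector 0.1*(i+1) * ones."""
    acts = np.zeros((6, 16, 7))
    for i in range(6):
        acts[i] = 0.1 * (i + 1)
    return TrialSet(acts)


def make_trialset(acts, **kw):
    return TrialSet(np.asarray(acts, dtype=float), **kw)
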