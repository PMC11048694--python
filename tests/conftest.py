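import warnings

import numpy as np
import pytest

from skillcurve import curves, synth


@pytest.fixture(scope="session")
def tiny_mcmc():
    """Small sampler profile for fast unit tests."""
    return curves.MCMCConfig(chains=2, iterations=600, warmup=250, seed=7)


@pytest.fixture(scope="session")
def reduced_mcmc():
    return curves.REDUCED_CONFIG


@pytest.fixture(scope="session")
def default_study():
    """One default-condition synthetic study, shared across tests."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return synth.simulate_study(seed=2024, with_events=False)


@pytest.fixture(scope="session")
def small_study():
    """Smaller study (n=30) for pipeline smoke tests."""
    cfg = synth.SynthConfig(n_participants=30, gaze_missing=4, seed=11)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return synth.simulate_study(cfg, with_events=False)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
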