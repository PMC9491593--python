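import numpy as np
import pytest

from stpfit import TMParameters, generate_dataset, plasticity_presets


@pytest.fixture
def mixed_params() -> TMParameters:
    """A moderately facilitating-then-depressing reference synapse."""
    return plasticity_presets()["mixed"]


@pytest.fixture
def reference_params() -> TMParameters:
    """The worked-example parameter set used across simulation tests."""
    return TMParameters(f=0.1, U=0.2, F=0.5, D=0.2, A=1.0, tau_syn=0.003)


@pytest.fixture
def noiseless_dataset(mixed_params):
    return generate_dataset(mixed_params, n_pulses=100, noise_sd_frac=0.0, seed=0)


@pytest.fixture
def rng():
    return np.random.default_rng(2026)
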