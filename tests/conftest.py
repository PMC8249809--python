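import numpy as np
import pytest

from renmm import IntegrationSpec, ModelParameters, initial_state, simulate


@pytest.fixture(scope="session")
def nominal_params() -> ModelParameters:
    return ModelParameters()


@pytest.fixture(scope="session")
def quiet_params() -> ModelParameters:
    """Nominal parameters with all noise sources off (deterministic)."""
    return ModelParameters().replace(phi_p_sd=0.0, phi_t_sd=0.0, phi_n_sd=0.0)


@pytest.fixture(scope="session")
def short_mixed_eeg(nominal_params):
    """One 30-s mixed-regime record shared across feature tests."""
    spec = IntegrationSpec(duration=40.0, burn_in=10.0, seed=7)
    return simulate(nominal_params, spec)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


@pytest.fixture()
def random_state(rng):
    """A physiologically plausible random model state."""
    y = initial_state(ModelParameters())
    y[:5] += rng.uniform(-15.0, 10.0, size=5)
    y[5:27] += rng.uniform(0.0, 0.5, size=22)
    y[27:33] += rng.uniform(0.0, 0.1, size=6)
    y[33:37] = rng.uniform(0.05, 0.9, size=4)
    return y
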