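import numpy as np
import pytest

from medci import Condition, compute_moments, generate_dataset


@pytest.fixture(scope="session")
def simple_dataset():
    """A medium-effect simple-mediation sample, normal predictor, n=100."""
    cond = Condition("simple", 100, 0.6, 0.6, 0.0, "normal")
    return generate_dataset(cond, 42)


@pytest.fixture(scope="session")
def simple_moments(simple_dataset):
    return compute_moments(simple_dataset)


@pytest.fixture(scope="session")
def serial_dataset():
    """A serial-mediation sample with a direct effect, n=150."""
    cond = Condition("serial", 150, 0.6, 0.36, 0.02, "normal")
    return generate_dataset(cond, 7)


@pytest.fixture(scope="session")
def serial_moments(serial_dataset):
    return compute_moments(serial_dataset)


@pytest.fixture()
def rng():
    return np.random.default_rng(20201218)
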