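import numpy as np
import pytest

from gradstate import planted_two_state_model
from gradstate.mem import MEMModel


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def planted_model():
    """Two-minimum model: State1 (DMN+Limbic+FPN_A) vs its complement."""
    return planted_two_state_model()


def random_model(n: int, rng: np.random.Generator, scale: float = 1.0) -> MEMModel:
    """Random symmetric model with |h|, |J| <= scale."""
    h = rng.uniform(-scale, scale, n)
    J = rng.uniform(-scale, scale, (n, n))
    J = 0.5 * (J + J.T)
    np.fill_diagonal(J, 0.0)
    return MEMModel(h=h, J=J, networks=tuple(f"net{i}" for i in range(n)))
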