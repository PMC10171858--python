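import numpy as np
import pytest
from hypothesis import settings

settings.register_profile(
    "ci", deadline=None, derandomize=True, max_examples=50
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_model(rng):
    """Random N=4 Ising model with two-sided labels."""
    from artr import IsingModel

    n = 4
    h = rng.uniform(-2, 1, n)
    J = np.zeros((n, n))
    iu = np.triu_indices(n, k=1)
    J[iu] = rng.uniform(-1, 1, iu[0].size)
    J += J.T
    return IsingModel(h, J, side=["L", "L", "R", "R"])


@pytest.fixture
def pair_model():
    """The N=2 worked example: h=0, J12=ln 2, so Z=5 and P(1,1)=0.4."""
    from artr import IsingModel

    return IsingModel([0.0, 0.0], [[0.0, np.log(2)], [np.log(2), 0.0]])


@pytest.fixture
def bistable_mf():
    from artr import MeanFieldModel

    return MeanFieldModel(HL=-5.0, HR=-5.0, JL=1.2, JR=1.2, KL=10.0, KR=10.0, I=-0.05)
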