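import numpy as np
import pytest

from mesnet import synthetic
from mesnet.config import RunConfig
from mesnet.containers import ExpressionMatrix


@pytest.fixture(scope="session")
def default_truth():
    """Planted instance at the generator's default study conditions."""
    return synthetic.generate_truth(seed=11)


@pytest.fixture(scope="session")
def small_cohorts(default_truth):
    truth, _, _ = default_truth
    lo, hi = synthetic.simulate_expression(truth, 20, 0.5, seed=12)
    return lo, hi


@pytest.fixture()
def config():
    return RunConfig(seed=0)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)


@pytest.fixture()
def tiny_expr():
    return ExpressionMatrix(
        ["g1", "g2", "g3"], ["s1", "s2"],
        np.array([[1.0, 2.0], [3.0, 4.0], [5.0, 6.0]]))
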