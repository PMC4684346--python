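import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def quadratic_ds():
    """The 50 x 10 quadratic-dependence dataset at a fixed seed."""
    from copulaforest import generate_quadratic_example

    return generate_quadratic_example(seed=7)


@pytest.fixture
def tiny_ds():
    """A deterministic 8 x 3 dataset with two responses."""
    from copulaforest import Dataset

    X = np.array([
        [0.1, 1.0, 5.0],
        [0.2, 0.9, 4.0],
        [0.3, 1.1, 3.0],
        [0.4, 0.8, 2.0],
        [0.5, 1.2, 1.0],
        [0.6, 0.7, 0.5],
        [0.7, 1.3, 0.2],
        [0.8, 0.6, 0.1],
    ])
    Y = np.column_stack([X[:, 0] * 2 + X[:, 2], (X[:, 0] - 0.45) ** 2])
    return Dataset([f"s{i}" for i in range(8)], X, Y)
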