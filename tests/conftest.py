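import numpy as np
import pytest

from isoleaf import (
    RunConfig,
    default_greenhouse_config,
    generate_greenhouse_dataset,
)


@pytest.fixture(scope="session")
def greenhouse():
    """One default greenhouse simulation shared across the suite."""
    config = default_greenhouse_config(seed=11)
    sset, records = generate_greenhouse_dataset(config)
    return config, sset, records


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


@pytest.fixture()
def small_problem(rng):
    """A small PLS problem with two planted latent components."""
    n, p = 40, 25
    T = rng.normal(size=(n, 2))
    P = rng.normal(size=(p, 2))
    X = T @ P.T + 0.05 * rng.normal(size=(n, p))
    y = 2.0 * T[:, 0] - 1.0 * T[:, 1] + 0.05 * rng.normal(size=n)
    return X, y
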