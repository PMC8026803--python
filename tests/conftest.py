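import numpy as np
import pytest

import foragesim as fs


@pytest.fixture(scope="session")
def grid():
    return fs.TransectGrid()


@pytest.fixture(scope="session")
def given_model():
    return fs.build_gradient_model("given")


@pytest.fixture(scope="session")
def alt_model():
    return fs.build_gradient_model("alternative")


@pytest.fixture(scope="session")
def noise():
    return fs.NoiseModel()


@pytest.fixture(scope="session")
def given_dataset(given_model, noise, grid):
    return fs.generate_dataset(given_model, noise, grid, seed=1)


@pytest.fixture(scope="session")
def alt_dataset(alt_model, noise, grid):
    return fs.generate_dataset(alt_model, noise, grid, seed=1)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
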