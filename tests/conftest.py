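import numpy as np
import pytest

from fatepattern.params import ModelParams, default_params
from fatepattern.signaling import neighbor_mean_kernel
from fatepattern.tissue import contact_graph, generate_disc_tissue


@pytest.fixture(scope="session")
def params() -> ModelParams:
    return default_params()


@pytest.fixture(scope="session")
def disc_tissue():
    """The reference 177-cell disc tissue (fixed seed) and its graph."""
    tissue = generate_disc_tissue(177, seed=42)
    return tissue, contact_graph(tissue)


@pytest.fixture(scope="session")
def small_tissue():
    """A small disc tissue for O(N^2)/Jacobian-sized checks."""
    tissue = generate_disc_tissue(25, seed=7)
    return tissue, contact_graph(tissue)


@pytest.fixture(scope="session")
def small_kernel(small_tissue):
    return neighbor_mean_kernel(small_tissue[1])


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
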