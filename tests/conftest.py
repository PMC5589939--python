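import numpy as np
import pytest

from brainmux.netbuild import build_multiplex
from brainmux.synthetic import CohortSpec


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_weighted(rng):
    """Symmetric zero-diagonal weight matrix in [0, 1], n=20."""
    n = 20
    W = rng.random((n, n))
    W = (W + W.T) / 2.0
    np.fill_diagonal(W, 0.0)
    return W


@pytest.fixture
def small_multiplex(rng):
    from oracles import random_multiplex

    return build_multiplex(random_multiplex(rng, n=12, M=3))


@pytest.fixture
def tiny_spec():
    return CohortSpec(
        n_hc=5,
        n_ad=5,
        n_nodes=20,
        n_layers=7,
        module_sizes=(5, 5, 5, 5),
        affected_nodes=tuple(range(5)),
        delta=0.5,
        seed=7,
    )
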