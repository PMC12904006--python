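import numpy as np
import pytest

import reggain as rg


@pytest.fixture(scope="session")
def tiny_case():
    """Small self-consistent synthetic case shared across tests."""
    return rg.make_benchmark_case("tiny", seed=7)


@pytest.fixture(scope="session")
def tiny_inputs(tiny_case):
    """Normalized expression + hub-partitioned prior for the tiny case."""
    X = rg.normalize_expression(tiny_case.expression)
    net = rg.identify_hubs(tiny_case.prior)
    return X, net


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def random_digraph(rng, n, p=0.3):
    """Dense random directed adjacency without self-loops."""
    a = (rng.random((n, n)) < p).astype(float)
    np.fill_diagonal(a, 0.0)
    return a
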