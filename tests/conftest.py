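import numpy as np
import pytest

from wheattrade import CountryPool, TradeNetwork


def build_network(n: int, edges) -> TradeNetwork:
    net = TradeNetwork(CountryPool.default(n))
    for i, j in edges:
        net.add_edge(i, j)
    return net


@pytest.fixture
def rng():
    return np.random.default_rng(20260925)


@pytest.fixture
def small_pool():
    return CountryPool.default(5)


@pytest.fixture
def triangle_net():
    # undirected triangle realised as 3 directed edges
    return build_network(4, [(0, 1), (1, 2), (2, 0)])


def random_directed_network(n: int, m: int,
                            rng: np.random.Generator) -> TradeNetwork:
    """Uniform random simple directed graph with exactly m edges."""
    pairs = [(i, j) for i in range(n) for j in range(n) if i != j]
    chosen = rng.choice(len(pairs), size=min(m, len(pairs)), replace=False)
    return build_network(n, [pairs[k] for k in chosen])
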