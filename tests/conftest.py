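import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from mcnet.rv import CorrelationNetwork

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_random_network(k: int, rng: np.random.Generator, density: float = 0.5):
    """Random weighted undirected network with weights in (0, 1]."""
    w = np.zeros((k, k))
    iu = np.triu_indices(k, 1)
    m = len(iu[0])
    vals = np.where(rng.random(m) < density, rng.random(m), 0.0)
    w[iu] = vals
    w += w.T
    return CorrelationNetwork(tuple(f"N{i}" for i in range(k)), w)


@pytest.fixture(scope="session")
def two_clique_network():
    """Two disjoint 3-cliques with unit weights: the canonical planted bipartition."""
    w = np.zeros((6, 6))
    for a, b in [(0, 1), (0, 2), (1, 2), (3, 4), (3, 5), (4, 5)]:
        w[a, b] = w[b, a] = 1.0
    return CorrelationNetwork(("A", "B", "C", "D", "E", "F"), w)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
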