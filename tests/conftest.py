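import networkx as nx
import numpy as np
import pytest

from dissentnet.core import DecisionParams
from dissentnet.dynamics import Population


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_ba(rng):
    from dissentnet.netgen import generate_ba

    return generate_ba(100, 5, rng)


def make_population(
    graph: nx.Graph,
    delta_o,
    w,
    sigma,
    beta: float = 100.0,
    subpop_ids=None,
    subpop_names=None,
) -> Population:
    n = graph.number_of_nodes()
    return Population.from_arrays(
        graph,
        np.broadcast_to(np.asarray(delta_o, float), (n,)).copy(),
        np.broadcast_to(np.asarray(w, float), (n,)).copy(),
        np.broadcast_to(np.asarray(sigma, int), (n,)).copy(),
        subpop_ids=subpop_ids,
        subpop_names=subpop_names,
        params=DecisionParams(beta=beta),
    )
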