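import networkx as nx
import numpy as np
import pytest

from httnet import HTTNetwork, SimConfig, generate_network
from httnet.fixtures import block_beta, tiny_net, toy_presence


@pytest.fixture
def two_node_net():
    g = nx.Graph()
    g.add_nodes_from([1, 2])
    g.add_edge(1, 2, weight=1.0)
    for n in g.nodes:
        g.nodes[n]["capacity"] = 10
    return HTTNetwork(g)


@pytest.fixture
def tiny_network():
    return tiny_net()


@pytest.fixture
def block_beta_matrix():
    return block_beta()


@pytest.fixture
def toy_presence_matrix():
    return toy_presence(seed=0)


@pytest.fixture
def sf20():
    """A connected 20-species scale-free network."""
    return generate_network("scale_free", 20, mean_degree=4, seed=7)


@pytest.fixture
def small_config():
    """Fast multi-family configuration for unit tests."""
    return SimConfig(
        n_species=6, n_families=8, capacity=20, target_htt_count=20,
        max_iterations=20_000, seed=3,
    )
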