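import networkx as nx
import pytest

from aidnet.simulate import SimulationConfig


@pytest.fixture
def bridged_triangles() -> nx.Graph:
    """Two triangles joined by one edge; optimal partition = the triangles."""
    return nx.Graph([(0, 1), (1, 2), (2, 0), (3, 4), (4, 5), (5, 3), (0, 3)])


@pytest.fixture
def two_cliques() -> nx.Graph:
    """Disjoint K4 + K4."""
    g = nx.complete_graph(4)
    g.update(nx.relabel_nodes(nx.complete_graph(4), {i: i + 4 for i in range(4)}))
    return g


@pytest.fixture
def small_graph_suite() -> list[nx.Graph]:
    """Fixture set of graphs with <= 8 nodes for brute-force comparisons."""
    bridged = nx.Graph([(0, 1), (1, 2), (2, 0), (3, 4), (4, 5), (5, 3), (0, 3)])
    two_k4 = nx.complete_graph(4)
    two_k4.update(nx.relabel_nodes(nx.complete_graph(4), {i: i + 4 for i in range(4)}))
    barbell = nx.barbell_graph(3, 1)  # K3 - path node - K3 (7 nodes)
    return [
        bridged,
        two_k4,
        barbell,
        nx.cycle_graph(6),
        nx.path_graph(5),
        nx.star_graph(5),
        nx.complete_graph(5),
        nx.cubical_graph(),  # 3-cube, 8 nodes, vertex-transitive
    ]


@pytest.fixture
def small_config() -> SimulationConfig:
    """Desk-scale study conditions used across the synthetic tests."""
    return SimulationConfig(seed=11)


def random_graph(seed: int, n_max: int = 30, connected_bias: float = 0.15) -> nx.Graph:
    """Seeded Erdos-Renyi graph with 4..n_max nodes and at least one edge."""
    import random

    rng = random.Random(seed)
    n = rng.randint(4, n_max)
    p = max(connected_bias, rng.random() * 0.5)
    g = nx.gnp_random_graph(n, p, seed=seed)
    while g.number_of_edges() == 0:
        p = min(1.0, p + 0.2)
        g = nx.gnp_random_graph(n, p, seed=seed + 1000)
    return g
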