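import networkx as nx
import pytest

from ppitopo.graph_core import Network, build_network


@pytest.fixture
def path4() -> Network:
    """Path graph A-B-C-D."""
    return build_network([("A", "B"), ("B", "C"), ("C", "D")])


@pytest.fixture
def square() -> Network:
    """4-cycle A-B-C-D-A."""
    return build_network([("A", "B"), ("B", "C"), ("C", "D"), ("D", "A")])


@pytest.fixture
def bridged_cliques() -> Network:
    """Two triangles joined through bridge node B: the classic bottleneck motif."""
    edges = [("A1", "A2"), ("A1", "A3"), ("A2", "A3"),
             ("C1", "C2"), ("C1", "C3"), ("C2", "C3"),
             ("B", "A1"), ("B", "C1")]
    return build_network(edges)


def as_network(g: nx.Graph) -> Network:
    return build_network(g.edges, extra_nodes=g.nodes)
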