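import networkx as nx
import pytest


def random_graph(n, p, seed):
    """Erdős–Rényi graph used as a neutral test substrate."""
    return nx.gnp_random_graph(n, p, seed=seed)


@pytest.fixture
def path5():
    """Path A-B-C-D-E as integers 0-4."""
    return nx.path_graph(5)


@pytest.fixture
def star5():
    """Star with hub 0 and leaves 1-4."""
    return nx.star_graph(4)
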