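import networkx as nx
import pandas as pd
import pytest

from gibbshomology import ProteinNetwork
from gibbshomology.expression import from_frame


@pytest.fixture
def triangle():
    return ProteinNetwork([("A", "B"), ("B", "C"), ("C", "A")])


@pytest.fixture
def path4():
    return ProteinNetwork([("A", "B"), ("B", "C"), ("C", "D")])


@pytest.fixture
def k5():
    g = nx.complete_graph(5)
    return ProteinNetwork(((f"N{a}", f"N{b}") for a, b in g.edges))


@pytest.fixture
def toy_table():
    df = pd.DataFrame(
        {"s1": [5.0, 10.0, 15.0], "s2": [1.0, 1.0, 1.0]},
        index=["A", "B", "C"],
    )
    return from_frame(df)


def random_network(n: int, p: float, seed: int) -> ProteinNetwork:
    g = nx.gnp_random_graph(n, p, seed=seed)
    net = ProteinNetwork(
        ((f"N{a:02d}", f"N{b:02d}") for a, b in g.edges),
        nodes=(f"N{i:02d}" for i in range(n)),
    )
    return net
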