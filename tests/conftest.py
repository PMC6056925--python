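import networkx as nx
import numpy as np
import pytest

from mgnet import InteractionNetwork, ScenarioConfig


@pytest.fixture
def triangle() -> InteractionNetwork:
    return InteractionNetwork.from_edges([("A", "B"), ("B", "C"), ("A", "C")],
                                         name="triangle")


@pytest.fixture
def path_abc() -> InteractionNetwork:
    return InteractionNetwork.from_edges([("A", "B"), ("B", "C")], name="path")


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260930)


def random_network(rng: np.random.Generator, n_nodes: int, p: float,
                   name: str = "random") -> InteractionNetwork:
    """Erdős–Rényi graph over symbols N00..; deterministic given rng state."""
    nodes = [f"N{i:02d}" for i in range(n_nodes)]
    edges = [(a, b) for i, a in enumerate(nodes) for b in nodes[i + 1:]
             if rng.random() < p]
    g = nx.Graph()
    g.add_nodes_from(nodes)
    g.add_edges_from(edges)
    return InteractionNetwork(g, name=name)


@pytest.fixture
def small_scenario_config() -> ScenarioConfig:
    """Down-scaled scenario for fast end-to-end tests."""
    return ScenarioConfig(n_nodes=200, n_immune_seeds=30, n_disease_seeds=15,
                          n_background_de=10)
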