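import numpy as np
import pytest

from areatrend.panel import AdjacencyGraph, ArealPanel
from areatrend.simulate import (
    SimulationScenario,
    denmark_like_graph,
    lattice_graph,
    ring_graph,
    simulate_panel,
)


@pytest.fixture
def path4():
    """Path graph 1-2-3-4."""
    return AdjacencyGraph.from_edges(["1", "2", "3", "4"], [("1", "2"), ("2", "3"), ("3", "4")])


@pytest.fixture
def ring6():
    return ring_graph(6)


@pytest.fixture(scope="session")
def lattice100():
    return lattice_graph(100)


@pytest.fixture(scope="session")
def dk94():
    return denmark_like_graph(94, seed=11)


@pytest.fixture
def tiny_panel():
    """3 units x 2 periods with one covariate, hand-checkable numbers."""
    y = np.array([[2, 3], [5, 4], [1, 6]])
    n = np.array([[10, 10], [10, 10], [10, 10]])
    cov = {"ami_age": np.array([[2.0, 1.0], [4.0, 2.0], [6.0, 3.0]])}
    return ArealPanel(("A", "B", "C"), ("P1", "P2"), y, n, cov)


@pytest.fixture(scope="session")
def small_sim():
    """Small simulated panel + graph + truth for fast model tests."""
    scenario = SimulationScenario(K=30, T=6, n_trials=300, seed=42)
    graph = denmark_like_graph(30, seed=42)
    panel, truth = simulate_panel(scenario, graph=graph)
    return panel, graph, truth
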