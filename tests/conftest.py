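import numpy as np
import pytest

from hoss.model import NetworkModel, SpeciesDef, mass_action_reaction
from hoss.synth import generate_synthetic_cascade, generate_synthetic_experiments


@pytest.fixture
def ab_reversible() -> NetworkModel:
    """Closed A <-> B with kf=2, kb=1, A0=3: steady state (1, 2)."""
    m = NetworkModel(
        species=[SpeciesDef("A", initial_conc=3.0), SpeciesDef("B")],
        reactions=[mass_action_reaction("r1", {"A": 1}, {"B": 1}, kf=2.0, kb=1.0)],
    )
    m.validate()
    return m


@pytest.fixture
def mm_motif_model() -> NetworkModel:
    """Single Michaelis-Menten motif with km = (4+1)/5 = 1 and scarce enzyme."""
    m = NetworkModel(
        species=[
            SpeciesDef("S", initial_conc=1.0),
            SpeciesDef("E", initial_conc=1e-3),
            SpeciesDef("ES"),
            SpeciesDef("P"),
        ],
        reactions=[
            mass_action_reaction("bind", {"S": 1, "E": 1}, {"ES": 1}, kf=5.0, kb=4.0),
            mass_action_reaction("cat", {"ES": 1}, {"P": 1, "E": 1}, kf=1.0),
        ],
    )
    m.validate()
    return m


@pytest.fixture(scope="session")
def cascade3():
    """Seeded 3-tier cascade with noiseless per-tier time-series experiments."""
    model, truth = generate_synthetic_cascade(n_tiers=3, species_per_tier=1, seed=7)
    experiments = generate_synthetic_experiments(model, truth, noise_sd=0.0, seed=0)
    return model, truth, experiments


def random_digraph(rng: np.random.Generator, n_max: int = 12) -> "nx.DiGraph":
    import networkx as nx

    n = int(rng.integers(2, n_max + 1))
    p = float(rng.uniform(0.1, 0.5))
    g = nx.DiGraph()
    g.add_nodes_from(range(n))
    for i in range(n):
        for j in range(n):
            if i != j and rng.random() < p:
                g.add_edge(i, j)
    return g
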