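import itertools

import networkx as nx
import numpy as np
import pytest

from hoss.decompose import (
    DecompositionOptions,
    InteractionGraph,
    agony,
    assign_levels_longest_path,
    auto_decompose,
    build_interaction_graph,
    check_autonomous_pair,
    consolidate_r_blocks,
    minimize_agony,
    nested_sets_from_levels,
    quotient_graph,
    r_causal_blocks,
    strongly_connected_components,
)
from hoss.model import NetworkModel, SpeciesDef, mass_action_reaction
from hoss.synth import generate_synthetic_cascade

from conftest import random_digraph


def brute_force_scc(g: nx.DiGraph):
    """Independent oracle: mutual reachability via boolean matrix closure."""
    nodes = sorted(g.nodes)
    n = len(nodes)
    idx = {v: i for i, v in enumerate(nodes)}
    R = np.eye(n, dtype=bool)
    for u, v in g.edges:
        R[idx[u], idx[v]] = True
    for _ in range(n):
        R = R | (R @ R)
    mutual = R & R.T
    comps = []
    seen = set()
    for i in range(n):
        if i in seen:
            continue
        comp = frozenset(nodes[j] for j in range(n) if mutual[i, j])
        seen |= {idx[v] for v in comp}
        comps.append(comp)
    return sorted(comps, key=min)


def as_ig(g: nx.DiGraph) -> InteractionGraph:
    return InteractionGraph(nodes=set(g.nodes), edges=set(g.edges))


# ---------------------------------------------------------------------------
# interaction graph
# ---------------------------------------------------------------------------

def test_interaction_graph_irreversible():
    m = NetworkModel(
        species=[SpeciesDef("A", initial_conc=1.0), SpeciesDef("B")],
        reactions=[mass_action_reaction("r1", {"A": 1}, {"B": 1}, kf=1.0)],
    )
    g = build_interaction_graph(m)
    assert g.edges == {("A", "A"), ("A", "B")}


def test_interaction_graph_reversible_forms_scc(ab_reversible):
    g = build_interaction_graph(ab_reversible)
    assert g.edges == {("A", "A"), ("A", "B"), ("B", "A"), ("B", "B")}
    assert strongly_connected_components(g) == [frozenset({"A", "B"})]


def test_interaction_graph_excludes_buffered():
    m = NetworkModel(
        species=[
            SpeciesDef("S", initial_conc=1.0),
            SpeciesDef("E", initial_conc=1.0, buffered=True),
            SpeciesDef("P"),
        ],
        reactions=[
            mass_action_reaction("v", {"S": 1}, {"P": 1}, kf=1.0)
        ],
    )
    m.reactions[0].rate_law = "kf*E*S"
    m.validate()
    g = build_interaction_graph(m)
    assert "E" not in g.nodes
    assert g.edges == {("S", "S"), ("S", "P")}


# ---------------------------------------------------------------------------
# SCC, quotient, levels
# ---------------------------------------------------------------------------

def test_scc_examples():
    g = nx.DiGraph([("a", "b"), ("b", "a"), ("b", "c")])
    assert strongly_connected_components(as_ig(g)) == [
        frozenset({"a", "b"}),
        frozenset({"c"}),
    ]
    dag = nx.DiGraph([("a", "b"), ("b", "c")])
    assert len(strongly_connected_components(as_ig(dag))) == 3
    cyc = nx.DiGraph([("a", "b"), ("b", "c"), ("c", "a")])
    assert strongly_connected_components(as_ig(cyc)) == [frozenset({"a", "b", "c"})]


def test_scc_matches_brute_force_oracle():
    rng = np.random.default_rng(42)
    for _ in range(200):
        g = random_digraph(rng, n_max=12)
        assert sorted(
            strongly_connected_components(as_ig(g)), key=min
        ) == brute_force_scc(g)


def test_quotient_graph_examples():
    g = nx.DiGraph([("a", "b"), ("b", "a"), ("b", "c")])
    q = quotient_graph(as_ig(g), [{"a", "b"}, {"c"}])
    assert q.number_of_nodes() == 2 and q.number_of_edges() == 1
    single = quotient_graph(as_ig(nx.DiGraph([("a", "b"), ("b", "a")])), [{"a", "b"}])
    assert single.number_of_nodes() == 1 and single.number_of_edges() == 0
    two = InteractionGraph(nodes={"a", "b"}, edges=set())
    assert quotient_graph(two, [{"a"}, {"b"}]).number_of_edges() == 0
    with pytest.raises(ValueError):
        quotient_graph(two, [{"a"}])


def test_quotient_of_exact_sccs_is_acyclic():
    rng = np.random.default_rng(1)
    for _ in range(50):
        g = random_digraph(rng, n_max=10)
        ig = as_ig(g)
        q = quotient_graph(ig, strongly_connected_components(ig))
        assert nx.is_directed_acyclic_graph(q)


def test_assign_levels_longest_path_diamond():
    """Two roots feeding a diamond: levels 0,0,1,2,2,3."""
    edges = [("A", "D"), ("B", "D"), ("D", "C"), ("D", "E"), ("C", "F"), ("E", "F")]
    q = nx.DiGraph(edges)
    levels = assign_levels_longest_path(q)
    assert levels == {"A": 0, "B": 0, "D": 1, "C": 2, "E": 2, "F": 3}


def test_assign_levels_edge_cases():
    q = nx.DiGraph()
    q.add_nodes_from("abc")
    assert assign_levels_longest_path(q) == {"a": 0, "b": 0, "c": 0}
    chain = nx.DiGraph([(i, i + 1) for i in range(5)])
    assert assign_levels_longest_path(chain) == {i: i for i in range(6)}
    with pytest.raises(ValueError):
        assign_levels_longest_path(nx.DiGraph([("a", "b"), ("b", "a")]))


# ---------------------------------------------------------------------------
# autonomous pairs
# ---------------------------------------------------------------------------

def test_check_autonomous_pair():
    m = NetworkModel(
        species=[SpeciesDef("A", initial_conc=1.0), SpeciesDef("B")],
        reactions=[mass_action_reaction("r1", {"A": 1}, {"B": 1}, kf=1.0)],
    )
    assert check_autonomous_pair(m, {"A"}, {"r1"}) == []
    bad = check_autonomous_pair(m, {"B"}, {"r1"})
    assert any("condition (ii)" in v and "A" in v for v in bad)
    assert check_autonomous_pair(m, {"A", "B"}, {"r1"}) == []


def test_nested_sets_cascade(cascade3):
    model = cascade3[0]
    decomp = auto_decompose(model)
    I_sets = decomp.nested_species_sets
    assert I_sets[0] == {"X11", "X11a"}
    assert I_sets[-1] == {s.id for s in model.species if not s.buffered}
    for a, b in zip(I_sets, I_sets[1:]):
        assert a < b  # strictly nested
    assert decomp.autonomy_warnings == []


# ---------------------------------------------------------------------------
# feedback machinery
# ---------------------------------------------------------------------------

def test_r_causal_blocks_cycle():
    ig = InteractionGraph(
        nodes={"a", "b", "c"}, edges={("a", "b"), ("b", "c"), ("c", "a")}
    )
    assert r_causal_blocks(ig, 1) == [
        frozenset({"a"}), frozenset({"b"}), frozenset({"c"})
    ]
    assert r_causal_blocks(ig, 2) == [frozenset({"a", "b", "c"})]


def test_r_inf_equals_scc():
    rng = np.random.default_rng(3)
    for _ in range(100):
        g = random_digraph(rng, n_max=8)
        ig = as_ig(g)
        assert sorted(r_causal_blocks(ig, None), key=min) == sorted(
            strongly_connected_components(ig), key=min
        )


def test_consolidate_r_blocks():
    assert consolidate_r_blocks([{"a", "b"}, {"b", "c"}]) == [frozenset("abc")]
    assert consolidate_r_blocks([{"a"}, {"b"}]) == [frozenset("a"), frozenset("b")]
    # chain of overlapping pairs collapses to one set (union-find oracle)
    chain = [{i, i + 1} for i in range(10)]
    assert consolidate_r_blocks(chain) == [frozenset(range(11))]


def test_agony_formula():
    dag = nx.DiGraph([("a", "b"), ("b", "c")])
    assert agony(dag, {"a": 0, "b": 1, "c": 2}) == 0
    two = nx.DiGraph([("a", "b"), ("b", "a")])
    assert agony(two, {"a": 0, "b": 0}) == 2
    one = nx.DiGraph([("u", "v")])
    assert agony(one, {"u": 3, "v": 1}) == 3
    with pytest.raises(ValueError):
        agony(one, {"u": 0})


def exhaustive_min_agony(g: nx.DiGraph) -> int:
    nodes = sorted(g.nodes)
    n = len(nodes)
    return min(
        agony(g, dict(zip(nodes, ranks)))
        for ranks in itertools.product(range(n), repeat=n)
    )


def test_minimize_agony_directed_cycles():
    for n in range(2, 7):
        g = nx.DiGraph([(i, (i + 1) % n) for i in range(n)])
        _, cost, _ = minimize_agony(g)
        assert cost == n == exhaustive_min_agony(g)


def test_minimize_agony_matches_exhaustive_search():
    rng = np.random.default_rng(11)
    for _ in range(40):
        g = random_digraph(rng, n_max=6)
        levels, cost, _ = minimize_agony(g)
        assert cost == exhaustive_min_agony(g)
        assert agony(g, levels) == cost
        assert min(levels.values()) == 0


def test_minimize_agony_dag_is_zero():
    g = nx.DiGraph([("a", "b"), ("b", "c"), ("a", "c")])
    levels, cost, _ = minimize_agony(g)
    assert cost == 0


def test_minimize_agony_designated_roots():
    g = nx.DiGraph([(0, 1), (1, 2), (2, 0)])
    levels, cost, warn = minimize_agony(g, designated_roots={1})
    assert cost == 3
    assert levels[1] == 0 and not warn


# ---------------------------------------------------------------------------
# auto decomposition
# ---------------------------------------------------------------------------

def test_auto_decompose_three_tier_three_wide():
    model, _ = generate_synthetic_cascade(n_tiers=3, species_per_tier=3, seed=5)
    decomp = auto_decompose(model)
    roots = [b for b in decomp.dynamic_blocks() if b.level == 0]
    assert len(roots) == 3
    assert decomp.max_level == 2


def test_auto_decompose_feedback_r1_splits():
    model, _ = generate_synthetic_cascade(
        n_tiers=3, species_per_tier=1, feedback={"strength": 1.0}, seed=5
    )
    graph = build_interaction_graph(model)
    assert len(strongly_connected_components(graph)) == 1  # exact SCC: one block
    decomp = auto_decompose(model, DecompositionOptions(r=1))
    assert len(decomp.dynamic_blocks()) > 1


def test_autonomy_and_containment_invariants():
    """Feed-forward fixtures: all pairs autonomous, blocks never straddle I sets."""
    rng = np.random.default_rng(17)
    for _ in range(50):
        tiers = int(rng.integers(1, 5))
        wide = int(rng.integers(1, 4))
        model, _ = generate_synthetic_cascade(
            n_tiers=tiers, species_per_tier=wide, seed=int(rng.integers(0, 10000))
        )
        decomp = auto_decompose(model)
        assert decomp.autonomy_warnings == []
        for I, J in zip(decomp.nested_species_sets, decomp.nested_reaction_sets):
            assert check_autonomous_pair(model, I, J) == []
            for blk in decomp.dynamic_blocks():
                inter = blk.members & I
                assert inter == set() or inter == set(blk.members)
        I_sets = decomp.nested_species_sets
        for a, b in zip(I_sets, I_sets[1:]):
            assert a < b
        roots = set().union(
            *(b.members for b in decomp.dynamic_blocks() if b.level == 0)
        )
        assert I_sets[0] == roots  # minimality


def test_auto_decompose_deterministic(cascade3):
    d1 = auto_decompose(cascade3[0])
    d2 = auto_decompose(cascade3[0])
    assert d1.to_json() == d2.to_json()
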