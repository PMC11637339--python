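"""Nested hierarchical decomposition of reaction networks.

The species interaction graph has an edge (j, i) whenever some reaction
consumes or produces i and its rate depends on the concentration of j.  In the
feed-forward case the strongly connected components (*blocks*) of this graph
form an acyclic quotient graph, and the longest path from the roots assigns
each block a hierarchy level; the union of blocks up to each level yields a
chain of nested *autonomous pairs* (I_0, J_0) subset ... subset (I_{K-1}, J_{K-1})
that can be optimized level by level.

Feedback collapses everything into one block.  To still obtain a usable
hierarchy, causality is restricted to paths of length <= r (*r-causality*),
overlapping r-blocks are consolidated into a partition, and hierarchy levels
on the (possibly cyclic) r-quotient graph are chosen to minimize *agony* — the
sum over edges of max(0, rank(u) - rank(v) + 1), which penalizes edges that
point down or sideways in the hierarchy.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import networkx as nx
import numpy as np

from .model import NetworkModel, rate_dependencies, stoichiometric_matrix

__all__ = [
    "InteractionGraph",
    "Block",
    "Decomposition",
    "DecompositionOptions",
    "build_interaction_graph",
    "strongly_connected_components",
    "quotient_graph",
    "assign_levels_longest_path",
    "nested_sets_from_levels",
    "check_autonomous_pair",
    "r_causal_blocks",
    "consolidate_r_blocks",
    "agony",
    "minimize_agony",
    "auto_decompose",
]


@dataclass
class InteractionGraph:
    """Directed species-interaction graph over non-buffered species."""

    nodes: Set[str]
    edges: Set[Tuple[str, str]]

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.edges)
        return g


@dataclass
class Block:
    id: str
    members: FrozenSet[str]
    level: int = -1
    is_input: bool = False  # buffered source block reported at level 0


@dataclass
class Decomposition:
    blocks: List[Block]
    nested_species_sets: List[Set[str]]
    nested_reaction_sets: List[Set[str]]
    r: Optional[int]  # None encodes r = infinity (exact SCC)
    used_agony: bool
    autonomy_warnings: List[str] = field(default_factory=list)

    @property
    def max_level(self) -> int:
        return max(b.level for b in self.blocks)

    def levels(self) -> Dict[str, int]:
        return {b.id: b.level for b in self.blocks}

    def dynamic_blocks(self) -> List[Block]:
        return [b for b in self.blocks if not b.is_input]

    def to_json(self) -> dict:
        return {
            "blocks": [
                {
                    "id": b.id,
                    "members": sorted(b.members),
                    "level": b.level,
                    "is_input": b.is_input,
                }
                for b in self.blocks
            ],
            "nested_species_sets": [sorted(s) for s in self.nested_species_sets],
            "nested_reaction_sets": [sorted(s) for s in self.nested_reaction_sets],
            "r": self.r,
            "used_agony": self.used_agony,
            "autonomy_warnings": self.autonomy_warnings,
        }

    def to_dot(self, qgraph: Optional[nx.DiGraph] = None) -> str:
        lines = ["digraph quotient {", "  rankdir=TB;"]
        for b in self.blocks:
            label = f"{b.id}\\nlevel {b.level}\\n{{{', '.join(sorted(b.members))}}}"
            shape = "box" if not b.is_input else "ellipse"
            lines.append(f'  "{b.id}" [label="{label}", shape={shape}];')
        if qgraph is not None:
            for u, v in sorted(qgraph.edges()):
                lines.append(f'  "{u}" -> "{v}";')
        lines.append("}")
        return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# graph construction
# ---------------------------------------------------------------------------

def build_interaction_graph(
    model: NetworkModel, include_buffered: bool = False
) -> InteractionGraph:
    """Edges (j, i): some reaction consumes or produces i and its rate depends on j.

    Buffered species are excluded as nodes (their dynamics are frozen); with
    ``include_buffered=True`` they are kept as pure sources (outgoing edges
    only), which is useful to display stimulus inputs at level 0.
    """
    buffered = model.buffered_ids()
    dynamic = {s.id for s in model.species if not s.buffered}
    nodes = set(dynamic) | (set() if not include_buffered else set())
    edges: Set[Tuple[str, str]] = set()
    for r in model.reactions:
        touched = (set(r.reactant_stoich) | set(r.product_stoich)) - buffered
        deps = rate_dependencies(model, r.id)
        for i in touched:
            for j in deps:
                if j in dynamic:
                    edges.add((j, i))
                elif include_buffered and j in buffered:
                    edges.add((j, i))
                    nodes.add(j)
    return InteractionGraph(nodes=nodes | dynamic, edges=edges)


def strongly_connected_components(graph: InteractionGraph) -> List[FrozenSet[str]]:
    """Maximal mutually-reachable sets, sorted by smallest member id."""
    comps = [frozenset(c) for c in nx.strongly_connected_components(graph.to_networkx())]
    return sorted(comps, key=lambda c: min(c))


def quotient_graph(
    graph: InteractionGraph, partition: Sequence[Iterable[str]]
) -> nx.DiGraph:
    """Directed graph over blocks; edge B1->B2 iff some member edge crosses them."""
    part = [frozenset(p) for p in partition]
    covered = set().union(*part) if part else set()
    if covered != graph.nodes:
        raise ValueError("partition does not cover the node set")
    owner: Dict[str, int] = {}
    for k, p in enumerate(part):
        for v in p:
            owner[v] = k
    names = [f"B{k}_{min(p)}" for k, p in enumerate(part)]
    q = nx.DiGraph()
    for k, p in enumerate(part):
        q.add_node(names[k], members=p)
    for u, v in graph.edges:
        if owner[u] != owner[v]:
            q.add_edge(names[owner[u]], names[owner[v]])
    return q


def assign_levels_longest_path(qgraph: nx.DiGraph) -> Dict[str, int]:
    """Level = length of the longest path from any root; roots get 0."""
    if not nx.is_directed_acyclic_graph(qgraph):
        raise ValueError("quotient graph is cyclic; use agony-based levelling")
    levels: Dict[str, int] = {}
    for node in nx.topological_sort(qgraph):
        preds = list(qgraph.predecessors(node))
        levels[node] = 0 if not preds else 1 + max(levels[p] for p in preds)
    return levels


# ---------------------------------------------------------------------------
# autonomous pairs and nested sets
# ---------------------------------------------------------------------------

def check_autonomous_pair(
    model: NetworkModel, I: Set[str], J: Set[str]
) -> List[str]:
    """Return a list of violations (empty means the pair is autonomous).

    Condition (i): every reaction that consumes or produces a species of I is
    in J.  Condition (ii): every non-buffered species a rate of J depends on
    is in I.
    """
    buffered = model.buffered_ids()
    violations: List[str] = []
    for r in model.reactions:
        touched = set(r.reactant_stoich) | set(r.product_stoich)
        if (touched - buffered) & I and r.id not in J:
            for sid in sorted((touched - buffered) & I):
                violations.append(
                    f"condition (i): species {sid} touched by reaction {r.id} not in J"
                )
    for rid in sorted(J):
        for dep in sorted(rate_dependencies(model, rid)):
            if dep not in I and dep not in buffered:
                violations.append(
                    f"condition (ii): rate of {rid} depends on {dep} outside I"
                )
    return violations


def _reactions_touching(model: NetworkModel, species: Set[str]) -> Set[str]:
    buffered = model.buffered_ids()
    out: Set[str] = set()
    for r in model.reactions:
        touched = (set(r.reactant_stoich) | set(r.product_stoich)) - buffered
        if touched & species:
            out.add(r.id)
    return out


def nested_sets_from_levels(
    model: NetworkModel, blocks: Sequence[Block]
) -> Tuple[List[Set[str]], List[Set[str]], List[str]]:
    """Build I_l / J_l chains from levelled blocks and check autonomy.

    I_l is the union of all non-input blocks with level <= l; J_l is every
    reaction consuming or producing a species of I_l.  Returns the two chains
    plus any autonomy violations (expected only when feedback edges had to be
    broken).
    """
    dyn = [b for b in blocks if not b.is_input]
    level_values = sorted({b.level for b in dyn})
    I_sets: List[Set[str]] = []
    J_sets: List[Set[str]] = []
    warnings: List[str] = []
    for l in level_values:
        I = set().union(*(b.members for b in dyn if b.level <= l))
        J = _reactions_touching(model, I)
        I_sets.append(I)
        J_sets.append(J)
        for v in check_autonomous_pair(model, I, J):
            warnings.append(f"level {l}: {v}")
    return I_sets, J_sets, warnings


# ---------------------------------------------------------------------------
# feedback: r-causality, consolidation, agony
# ---------------------------------------------------------------------------

def r_causal_blocks(
    graph: InteractionGraph, r: Optional[int]
) -> List[FrozenSet[str]]:
    """Maximal sets of pairwise mutually r-causal species (may overlap).

    Every species is self-causal.  Mutual r-causality is not transitive, so the
    blocks are the maximal cliques of the mutual-reachability graph; with
    r = None (infinity) the relation is transitive and the result equals the
    strongly connected components.
    """
    if r is None:
        return strongly_connected_components(graph)
    if r < 1:
        raise ValueError("r must be >= 1")
    g = graph.to_networkx()
    nodes = sorted(graph.nodes)
    reach: Dict[str, Set[str]] = {}
    for u in nodes:
        # BFS truncated at depth r
        seen = {u: 0}
        frontier = [u]
        for depth in range(1, r + 1):
            nxt = []
            for w in frontier:
                for v in g.successors(w):
                    if v not in seen:
                        seen[v] = depth
                        nxt.append(v)
            frontier = nxt
        reach[u] = set(seen)
    mutual = nx.Graph()
    mutual.add_nodes_from(nodes)
    for u, v in itertools.combinations(nodes, 2):
        if v in reach[u] and u in reach[v]:
            mutual.add_edge(u, v)
    cliques = [frozenset(c) for c in nx.find_cliques(mutual)]
    return sorted(cliques, key=lambda c: (min(c), -len(c)))


def consolidate_r_blocks(blocks: Sequence[Iterable[str]]) -> List[FrozenSet[str]]:
    """Merge overlapping blocks (transitive closure of overlap) into a partition."""
    parent: Dict[str, str] = {}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(a: str, b: str) -> None:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[max(ra, rb)] = min(ra, rb)

    for blk in blocks:
        blk = list(blk)
        for v in blk:
            parent.setdefault(v, v)
        for v in blk[1:]:
            union(blk[0], v)
    groups: Dict[str, Set[str]] = {}
    for v in parent:
        groups.setdefault(find(v), set()).add(v)
    return sorted((frozenset(g) for g in groups.values()), key=min)


def agony(qgraph: nx.DiGraph, ranks: Mapping[str, int]) -> int:
    """Sum over edges (u, v) of max(0, rank(u) - rank(v) + 1)."""
    missing = [n for n in qgraph.nodes if n not in ranks]
    if missing:
        raise ValueError(f"missing rank for nodes: {sorted(missing)}")
    return sum(max(0, ranks[u] - ranks[v] + 1) for u, v in qgraph.edges())


def _normalize_levels(levels: Dict[str, int]) -> Dict[str, int]:
    """Relabel levels to be contiguous integers starting at 0."""
    used = sorted(set(levels.values()))
    remap = {l: k for k, l in enumerate(used)}
    return {n: remap[l] for n, l in levels.items()}


def minimize_agony(
    qgraph: nx.DiGraph,
    designated_roots: Optional[Set[str]] = None,
    _bb_limit: int = 12,
) -> Tuple[Dict[str, int], int, List[str]]:
    """Exact agony-minimizing levels for a (small) quotient graph.

    Returns (levels, minimum agony, warnings).  Among minimizers the solution
    assigning level 0 to designated roots is preferred, then the
    lexicographically smallest level vector over nodes sorted by id.  Levels
    are normalized to be contiguous from 0.  Exact branch-and-bound is used up
    to ``_bb_limit`` nodes; larger graphs fall back to an LP whose constraint
    matrix is totally unimodular (the optimum is integral), without the
    lexicographic tie-break.
    """
    nodes = sorted(qgraph.nodes)
    n = len(nodes)
    warnings: List[str] = []
    if n == 0:
        return {}, 0, warnings
    roots = set(designated_roots or ())

    if n <= _bb_limit:
        in_edges = {v: [u for u in qgraph.predecessors(v)] for v in nodes}
        out_edges = {v: [u for u in qgraph.successors(v)] for v in nodes}
        idx = {v: k for k, v in enumerate(nodes)}
        n_edges = qgraph.number_of_edges()

        # phase 1: minimum agony by branch and bound over rank vectors
        def min_cost(pin_roots: bool) -> Optional[int]:
            assign: List[Optional[int]] = [None] * n
            best = [None]

            def rec(k: int, cost: int) -> None:
                if best[0] is not None and cost >= best[0]:
                    return
                if k == n:
                    best[0] = cost
                    return
                v = nodes[k]
                choices = [0] if (pin_roots and v in roots) else range(n)
                for rank in choices:
                    add = 0
                    for u in in_edges[v]:
                        ru = assign[idx[u]]
                        if ru is not None:
                            add += max(0, ru - rank + 1)
                    for w in out_edges[v]:
                        rw = assign[idx[w]]
                        if rw is not None:
                            add += max(0, rank - rw + 1)
                    if best[0] is None or cost + add < best[0]:
                        assign[k] = rank
                        rec(k + 1, cost + add)
                        assign[k] = None

            rec(0, 0)
            return best[0]

        cost = min_cost(False)
        pin = False
        if roots:
            pinned_cost = min_cost(True)
            if pinned_cost is not None and pinned_cost == cost:
                pin = True
            else:
                warnings.append(
                    "designated roots cannot all sit at level 0 in a minimum-agony "
                    "ranking; root designation dropped"
                )

        # phase 2: among minimizers, maximize the number of strictly upward
        # (zero-penalty) edges, so a cycle of blocks still spreads into levels
        # instead of collapsing onto one; then take the lexicographically
        # smallest vector over nodes sorted by id.
        budget = [300_000]
        best_key: List[Optional[Tuple[int, Tuple[int, ...]]]] = [None]
        assign2: List[Optional[int]] = [None] * n

        def rec2(k: int, cost_so_far: int, upward: int, undecided: int) -> None:
            if budget[0] <= 0:
                return
            budget[0] -= 1
            if cost_so_far > cost:
                return
            if best_key[0] is not None and upward + undecided < -best_key[0][0]:
                return
            if k == n:
                if cost_so_far == cost:
                    key = (-upward, tuple(assign2))
                    if best_key[0] is None or key < best_key[0]:
                        best_key[0] = key
                return
            v = nodes[k]
            choices = [0] if (pin and v in roots) else range(n)
            for rank in choices:
                add = 0
                up_add = 0
                newly = 0
                for u in in_edges[v]:
                    ru = assign2[idx[u]]
                    if ru is not None:
                        newly += 1
                        pen = max(0, ru - rank + 1)
                        add += pen
                        if pen == 0:
                            up_add += 1
                for w in out_edges[v]:
                    rw = assign2[idx[w]]
                    if rw is not None:
                        newly += 1
                        pen = max(0, rank - rw + 1)
                        add += pen
                        if pen == 0:
                            up_add += 1
                assign2[k] = rank
                rec2(k + 1, cost_so_far + add, upward + up_add, undecided - newly)
                assign2[k] = None

        rec2(0, 0, 0, n_edges)
        assert best_key[0] is not None
        vec = best_key[0][1]
        levels = _normalize_levels({v: vec[k] for k, v in enumerate(nodes)})
        return levels, int(cost), warnings

    # LP fallback for large quotient graphs (rare: quotient graphs are small)
    from scipy.optimize import linprog

    edges = sorted(qgraph.edges())
    m = len(edges)
    nidx = {v: k for k, v in enumerate(nodes)}
    # variables: r_0..r_{n-1}, d_0..d_{m-1}; minimize sum d
    c = np.concatenate([np.zeros(n), np.ones(m)])
    A_ub = np.zeros((m, n + m))
    b_ub = np.zeros(m)
    for e, (u, v) in enumerate(edges):
        A_ub[e, nidx[u]] = 1.0
        A_ub[e, nidx[v]] = -1.0
        A_ub[e, n + e] = -1.0
        b_ub[e] = -1.0
    bounds = [(0, n - 1)] * n + [(0, None)] * m
    res = linprog(c, A_ub=A_ub, b_ub=b_ub, bounds=bounds, method="highs")
    if not res.success:  # pragma: no cover
        raise RuntimeError(f"agony LP failed: {res.message}")
    levels = _normalize_levels({v: int(round(res.x[nidx[v]])) for v in nodes})
    warnings.append("large quotient graph: LP solution, no lexicographic tie-break")
    return levels, agony(qgraph, {v: int(round(res.x[nidx[v]])) for v in nodes}), warnings


# ---------------------------------------------------------------------------
# automatic decomposition
# ---------------------------------------------------------------------------

@dataclass
class DecompositionOptions:
    r: Optional[int] = 1  # causality radius for feedback; None = exact SCC only
    use_agony: bool = True
    qss_reduce: bool = False
    irreversible_reactions: Sequence[str] = ()
    designated_roots: Optional[Set[str]] = None
    include_buffered_inputs: bool = True


def auto_decompose(
    model: NetworkModel, options: Optional[DecompositionOptions] = None
) -> Decomposition:
    """Compute a nested hierarchical decomposition of a model.

    QSS reduction and forward irreversibility, when requested, transform a
    *shadow* copy used only to define the hierarchy; the input model is never
    modified.  If the exact-SCC quotient already has more than one block,
    longest-path levels are used directly; otherwise the graph is re-blocked
    with r-causality, consolidated, and levelled by agony minimization.

    With ``include_buffered_inputs`` (default), buffered species appearing in
    rate laws of reactions that touch dynamic species are reported as
    singleton source blocks at level 0 and every dynamic level shifts up by
    one — matching the convention of displaying stimulus enzymes as the root
    tier.  The nested I/J sets always range over non-buffered species only.
    """
    opts = options or DecompositionOptions()
    shadow = model
    if opts.qss_reduce:
        from .reduction import qss_reduce

        shadow = qss_reduce(shadow)
    if opts.irreversible_reactions:
        from .reduction import apply_irreversibility_for_decomposition

        shadow = apply_irreversibility_for_decomposition(
            shadow, list(opts.irreversible_reactions)
        )

    graph = build_interaction_graph(shadow)
    used_agony = False
    r_used: Optional[int] = None

    sccs = strongly_connected_components(graph)
    if len(sccs) > 1 or len(graph.nodes) <= 1:
        partition = sccs
        q = quotient_graph(graph, partition)
        levels_by_name = assign_levels_longest_path(q)
    else:
        # single block: feedback entangles everything; re-block with r-causality
        r_used = opts.r if opts.r is not None else 1
        rblocks = r_causal_blocks(graph, r_used)
        partition = consolidate_r_blocks(rblocks)
        q = quotient_graph(graph, partition)
        if nx.is_directed_acyclic_graph(q) and not opts.use_agony:
            levels_by_name = assign_levels_longest_path(q)
        else:
            used_agony = True
            roots = None
            if opts.designated_roots:
                roots = set()
                for name, data in q.nodes(data=True):
                    if data["members"] & opts.designated_roots:
                        roots.add(name)
            levels_by_name, _, _warn = minimize_agony(q, designated_roots=roots)
        if len(partition) == 1:
            pass  # warning emitted below through autonomy machinery

    members_of = {name: data["members"] for name, data in q.nodes(data=True)}
    blocks = [
        Block(id=name, members=frozenset(members_of[name]), level=lvl)
        for name, lvl in sorted(levels_by_name.items())
    ]

    # optional buffered-input tier at level 0
    if opts.include_buffered_inputs:
        buffered = shadow.buffered_ids()
        inputs: Set[str] = set()
        for r in shadow.reactions:
            touched = (set(r.reactant_stoich) | set(r.product_stoich)) - buffered
            if not touched:
                continue
            inputs |= rate_dependencies(shadow, r.id) & buffered
        if inputs:
            for b in blocks:
                b.level += 1
            for sid in sorted(inputs):
                blocks.append(
                    Block(id=f"IN_{sid}", members=frozenset({sid}), level=0, is_input=True)
                )

    blocks.sort(key=lambda b: (b.level, b.id))
    I_sets, J_sets, warnings = nested_sets_from_levels(shadow, blocks)

    # species present in the full model but not in the shadow (e.g. complexes
    # eliminated by QSS reduction) are lifted into the block of their
    # highest-level non-buffered neighbour so the decomposition can be applied
    # back to the full model.
    missing = set(s.id for s in model.species if not s.buffered) - set(
        s.id for s in shadow.species
    )
    if missing:
        level_of: Dict[str, int] = {}
        for b in blocks:
            if not b.is_input:
                for sid in b.members:
                    level_of[sid] = b.level
        for sid in sorted(missing):
            neigh_levels = []
            for r in model.reactions:
                touched = set(r.reactant_stoich) | set(r.product_stoich) | set(r.modifiers)
                if sid in touched:
                    neigh_levels += [level_of[t] for t in touched if t in level_of]
            lvl = max(neigh_levels) if neigh_levels else min(
                (b.level for b in blocks if not b.is_input), default=0
            )
            host = next(b for b in blocks if not b.is_input and b.level == lvl)
            host.members = frozenset(host.members | {sid})
            level_of[sid] = lvl
        warnings.append(
            "species eliminated in the decomposition shadow were lifted into "
            f"neighbour blocks: {sorted(missing)}"
        )

    return Decomposition(
        blocks=blocks,
        nested_species_sets=I_sets,
        nested_reaction_sets=J_sets,
        r=r_used,
        used_agony=used_agony,
        autonomy_warnings=warnings,
    )


def write_decomposition_report(
    decomp: Decomposition, json_path: str, dot_path: Optional[str] = None,
    qgraph: Optional[nx.DiGraph] = None,
) -> None:
    with open(json_path, "w") as fh:
        json.dump(decomp.to_json(), fh, indent=1, sort_keys=True)
        fh.write("\n")
    if dot_path:
        with open(dot_path, "w") as fh:
            fh.write(decomp.to_dot(qgraph))
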