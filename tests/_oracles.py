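"""Independent brute-force oracles used across the test suite.

Everything here is built on exhaustive enumeration plus
:func:`signcons.model.satisfies` (a direct transcription of the
consistency rule) and never touches the engine's search code, so it can
serve as ground truth for the solver, the prediction tables, the MIC
finder and the repair search.
"""

from __future__ import annotations

from itertools import combinations, product

from signcons.model import (
    EdgeLabel,
    Instance,
    InfluenceGraph,
    ObservationSet,
    Sign,
    TotalLabeling,
    effective_inputs,
    free_variables,
    satisfies,
    sign_product,
)

SIGNS = (Sign.PLUS, Sign.MINUS)


def all_total_labelings(instance: Instance):
    """Every total labeling extending the observations and fixed labels."""
    free_nodes, free_edges = free_variables(instance)
    fixed_nodes = dict(instance.observations.signs)
    fixed_edges = {
        e: lab.sign
        for e, lab in instance.graph.edge_labels.items()
        if lab is not EdgeLabel.UNKNOWN
    }
    for node_vals in product(SIGNS, repeat=len(free_nodes)):
        for edge_vals in product(SIGNS, repeat=len(free_edges)):
            yield TotalLabeling(
                {**fixed_nodes, **dict(zip(free_nodes, node_vals))},
                {**fixed_edges, **dict(zip(free_edges, edge_vals))},
            )


def oracle_solutions(instance: Instance) -> list[TotalLabeling]:
    return [lab for lab in all_total_labelings(instance) if satisfies(lab, instance)]


def oracle_consistent(instance: Instance) -> bool:
    return any(satisfies(lab, instance) for lab in all_total_labelings(instance))


def oracle_predictions(instance: Instance):
    """Intersection of all solutions over the free variables.

    Returns ``(node_predictions, edge_predictions)`` or None when the
    instance is inconsistent.
    """
    sols = oracle_solutions(instance)
    if not sols:
        return None
    free_nodes, free_edges = free_variables(instance)
    node_preds = {}
    for v in free_nodes:
        seen = {lab.node_signs[v] for lab in sols}
        if len(seen) == 1:
            node_preds[v] = next(iter(seen))
    edge_preds = {}
    for e in free_edges:
        seen = {lab.edge_signs[e] for lab in sols}
        if len(seen) == 1:
            edge_preds[e] = next(iter(seen))
    return node_preds, edge_preds


# ---------------------------------------------------------------------------
# MIC oracle


def oracle_core_infeasible(instance: Instance, members: frozenset[str]) -> bool:
    """Brute-force infeasibility of a candidate core on its scope."""
    graph = instance.graph
    scope_edges = sorted(e for e in graph.edge_labels if e[1] in members)
    scope_nodes = sorted(members | {u for (u, _) in scope_edges})
    obs = instance.observations.signs
    free_nodes = [v for v in scope_nodes if v not in obs]
    free_edges = [
        e for e in scope_edges if graph.edge_labels[e] is EdgeLabel.UNKNOWN
    ]
    fixed_edges = {
        e: graph.edge_labels[e].sign for e in scope_edges if e not in free_edges
    }
    for node_vals in product(SIGNS, repeat=len(free_nodes)):
        node_signs = {**{v: obs[v] for v in scope_nodes if v in obs},
                      **dict(zip(free_nodes, node_vals))}
        for edge_vals in product(SIGNS, repeat=len(free_edges)):
            edge_signs = {**fixed_edges, **dict(zip(free_edges, edge_vals))}
            ok = all(
                any(
                    sign_product(node_signs[u], edge_signs[(u, m)]) is node_signs[m]
                    for (u, t) in scope_edges
                    if t == m
                )
                for m in members
            )
            if ok:
                return False
    return True


def oracle_mics(instance: Instance, max_size: int | None = None):
    """All minimal infeasible cores, by independent subset enumeration."""
    non_inputs = sorted(instance.graph.nodes - effective_inputs(instance.graph))
    if max_size is None:
        max_size = len(non_inputs)
    infeasible = []
    for size in range(1, min(max_size, len(non_inputs)) + 1):
        for combo in combinations(non_inputs, size):
            members = frozenset(combo)
            if oracle_core_infeasible(instance, members):
                infeasible.append(members)
    return sorted(
        (m for m in infeasible
         if not any(o < m for o in infeasible)),
        key=lambda m: (len(m), tuple(sorted(m))),
    )


# ---------------------------------------------------------------------------
# exhaustive instance sweep (tiny graphs)


def sweep_graphs(max_nodes: int = 3, max_edges: int = 4):
    """Every influence graph on ≤ ``max_nodes`` labelled nodes with
    ≤ ``max_edges`` edges (self-loops allowed) and every edge-label
    assignment over {+, -, ?}."""
    names = ["A", "B", "C", "D"][:max_nodes]
    for n in range(1, max_nodes + 1):
        nodes = names[:n]
        pairs = [(u, v) for u in nodes for v in nodes]
        for k in range(0, min(max_edges, len(pairs)) + 1):
            for edge_set in combinations(pairs, k):
                for labels in product(
                    (EdgeLabel.PLUS, EdgeLabel.MINUS, EdgeLabel.UNKNOWN),
                    repeat=k,
                ):
                    yield InfluenceGraph(
                        frozenset(nodes), dict(zip(edge_set, labels))
                    )


def observation_patterns(nodes):
    """Every partial sign assignment over ``nodes``."""
    nodes = sorted(nodes)
    for values in product((None, Sign.PLUS, Sign.MINUS), repeat=len(nodes)):
        yield ObservationSet(
            {v: s for v, s in zip(nodes, values) if s is not None}
        )


def graph_solutions_unconstrained(graph: InfluenceGraph):
    """All rule-satisfying total labelings of a graph, before observations.

    Shared across observation patterns: an instance with observations O
    is consistent iff some labeling here agrees with O.
    """
    blank = Instance(graph, ObservationSet({}))
    return oracle_solutions(blank)
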