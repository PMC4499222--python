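"""Minimal Inconsistent Cores (MICs).

A MIC is a minimal set of non-input nodes whose explanation requirements
cannot be met jointly: restricted to the members, their predecessors and
the edges into the members (with observations and fixed labels on that
scope), no labeling satisfies the rule at every member, yet every proper
nonempty subset of the members admits one.  MICs localise the parts of a
network responsible for an inconsistency.

Feasibility of a candidate is judged on the induced sub-problem only:
nodes outside the scope and the rule at non-member nodes do not bind.
Infeasibility is monotone under member-set inclusion, so enumeration by
increasing cardinality with superset pruning returns exactly the minimal
cores.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

from . import engine
from .model import (
    Edge,
    Instance,
    InfluenceGraph,
    ObservationSet,
    effective_inputs,
)

__all__ = ["MIC", "is_infeasible_core", "find_mics"]

DEFAULT_MAX_MIC_SIZE = 8


@dataclass(frozen=True)
class MIC:
    members: frozenset[str]
    scope_nodes: frozenset[str]
    scope_edges: frozenset[Edge]

    def sort_key(self) -> tuple[int, tuple[str, ...]]:
        return (len(self.members), tuple(sorted(self.members)))


def _scope(instance: Instance, members: frozenset[str]):
    graph = instance.graph
    scope_edges = frozenset(e for e in graph.edge_labels if e[1] in members)
    scope_nodes = members | {u for (u, _) in scope_edges}
    return scope_nodes, scope_edges


def _sub_instance(instance: Instance, members: frozenset[str]) -> Instance:
    """The induced sub-problem: the rule is enforced exactly at the members."""
    scope_nodes, scope_edges = _scope(instance, members)
    graph = instance.graph
    sub_graph = InfluenceGraph(
        nodes=scope_nodes,
        edge_labels={e: graph.edge_labels[e] for e in scope_edges},
        declared_inputs=scope_nodes - members,
    )
    sub_obs = ObservationSet(
        signs={
            v: s for v, s in instance.observations.signs.items() if v in scope_nodes
        }
    )
    return Instance(sub_graph, sub_obs)


def is_infeasible_core(instance: Instance, candidate: frozenset[str]) -> bool:
    """True iff no labeling of the candidate's scope explains every member."""
    candidate = frozenset(candidate)
    if not candidate:
        raise ValueError("candidate must be nonempty")
    inputs = effective_inputs(instance.graph)
    bad = candidate & inputs
    if bad:
        raise ValueError(
            f"candidate contains input nodes (exempt from the rule): {sorted(bad)}"
        )
    stray = candidate - instance.graph.nodes
    if stray:
        raise ValueError(f"candidate contains unknown nodes: {sorted(stray)}")
    return not engine.solve(_sub_instance(instance, candidate)).consistent


def find_mics(instance: Instance, max_size: int = DEFAULT_MAX_MIC_SIZE) -> list[MIC]:
    """All MICs with at most ``max_size`` members, smallest first.

    Consistent instances have no infeasible core and yield an empty
    list.  Results are sorted by (size, lexicographic members); no
    returned core is a subset of another.
    """
    if max_size < 1:
        raise ValueError("max_size must be positive")
    if engine.solve(instance).consistent:
        # a consistent global labeling restricts to every scope
        return []
    candidates = sorted(instance.graph.nodes - effective_inputs(instance.graph))
    found: list[frozenset[str]] = []
    for size in range(1, min(max_size, len(candidates)) + 1):
        for combo in combinations(candidates, size):
            members = frozenset(combo)
            if any(core <= members for core in found):
                continue
            if is_infeasible_core(instance, members):
                found.append(members)
    mics = []
    for members in found:
        scope_nodes, scope_edges = _scope(instance, members)
        mics.append(MIC(members, scope_nodes, scope_edges))
    return sorted(mics, key=MIC.sort_key)
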