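"""Core domain types for signed influence graphs.

An influence graph is a directed graph whose vertices are molecular
entities (genes, proteins, metabolites) and whose edges state that a
variation of the source influences the level of the target.  Edges carry
a sign: ``+`` for activation, ``-`` for inhibition, or ``?`` when the
mode of regulation is not known.  Experimental observations assign an
up (``+``) or down (``-``) variation to a subset of nodes, typically the
difference between two steady states after a perturbation.

The sign consistency rule enforced throughout this package is: the
variation of every node that is not an input must be explained by at
least one of its predecessors, i.e. some incoming edge whose source sign
multiplied by the edge sign equals the node's own sign.  Nodes declared
as inputs, and nodes without any incoming edge, are exempt.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping

__all__ = [
    "Sign",
    "EdgeLabel",
    "InfluenceGraph",
    "ObservationSet",
    "Instance",
    "TotalLabeling",
    "sign_product",
    "effective_inputs",
    "free_variables",
    "satisfies",
    "SignConsError",
    "GraphValidationError",
    "LabelingError",
]

Edge = tuple[str, str]


class SignConsError(Exception):
    """Base class for all errors raised by this package."""


class GraphValidationError(SignConsError):
    """An influence graph or instance violates a structural invariant."""


class LabelingError(SignConsError):
    """A labeling does not cover every node and edge of its instance."""


class Sign(enum.Enum):
    """Qualitative variation: up-regulation (``+``) or down-regulation (``-``)."""

    PLUS = 1
    MINUS = -1

    def __neg__(self) -> "Sign":
        return Sign(-self.value)

    @property
    def token(self) -> str:
        return "+" if self is Sign.PLUS else "-"

    @classmethod
    def from_int(cls, value: int) -> "Sign":
        if value > 0:
            return cls.PLUS
        if value < 0:
            return cls.MINUS
        raise ValueError("zero has no sign")

    def __repr__(self) -> str:  # compact in test diffs
        return f"Sign({self.token})"


def sign_product(a: Sign, b: Sign) -> Sign:
    """Product of two signs; PLUS is the identity, MINUS negates."""
    return Sign(a.value * b.value)


class EdgeLabel(enum.Enum):
    """Edge annotation: fixed activation/inhibition, or a free ``?`` variable.

    UNKNOWN is not a third sign; it marks an edge whose sign is left to
    the solver, exactly like an unobserved node.
    """

    PLUS = "+"
    MINUS = "-"
    UNKNOWN = "?"

    @property
    def sign(self) -> Sign | None:
        """The fixed sign this label imposes, or None for UNKNOWN."""
        if self is EdgeLabel.UNKNOWN:
            return None
        return Sign.PLUS if self is EdgeLabel.PLUS else Sign.MINUS

    @classmethod
    def from_sign(cls, s: Sign) -> "EdgeLabel":
        return cls.PLUS if s is Sign.PLUS else cls.MINUS

    def __repr__(self) -> str:
        return f"EdgeLabel({self.value})"


@dataclass(frozen=True)
class InfluenceGraph:
    """A signed directed graph with at most one edge per ordered pair.

    Parameters
    ----------
    nodes
        Unique node identifiers (case-sensitive strings).
    edge_labels
        Mapping from ordered pairs ``(source, target)`` to an
        :class:`EdgeLabel`.  Self-loops are permitted.
    declared_inputs
        Nodes exempted from the explanation rule by the user, e.g.
        experimentally perturbed genes.
    """

    nodes: frozenset[str]
    edge_labels: Mapping[Edge, EdgeLabel]
    declared_inputs: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        object.__setattr__(self, "nodes", frozenset(self.nodes))
        object.__setattr__(self, "edge_labels", dict(self.edge_labels))
        object.__setattr__(self, "declared_inputs", frozenset(self.declared_inputs))
        for (u, v) in self.edge_labels:
            if u not in self.nodes or v not in self.nodes:
                raise GraphValidationError(
                    f"edge ({u!r}, {v!r}) has an endpoint outside the node set"
                )
        extra = self.declared_inputs - self.nodes
        if extra:
            raise GraphValidationError(
                f"declared inputs not in node set: {sorted(extra)}"
            )

    @property
    def edges(self) -> Iterable[Edge]:
        return self.edge_labels.keys()

    def sorted_nodes(self) -> list[str]:
        return sorted(self.nodes)

    def sorted_edges(self) -> list[Edge]:
        return sorted(self.edge_labels)

    def predecessors(self, v: str) -> list[str]:
        return sorted(u for (u, w) in self.edge_labels if w == v)

    def in_degree(self, v: str) -> int:
        return sum(1 for (_, w) in self.edge_labels if w == v)

    def to_networkx(self):
        """Export as a :class:`networkx.DiGraph` with a ``sign`` edge attribute."""
        import networkx as nx

        g = nx.DiGraph()
        g.add_nodes_from(self.sorted_nodes())
        for (u, v), lab in sorted(self.edge_labels.items()):
            g.add_edge(u, v, sign=lab.value)
        return g


def effective_inputs(graph: InfluenceGraph) -> frozenset[str]:
    """Nodes exempt from the explanation rule.

    The union of the user-declared inputs and every node with in-degree
    zero: a node without predecessors can never be explained, so it is
    necessarily treated as an input.
    """
    targets = {v for (_, v) in graph.edge_labels}
    return graph.declared_inputs | (graph.nodes - targets)


@dataclass(frozen=True)
class ObservationSet:
    """A partial assignment of signs to nodes (the experimental profile).

    ``provenance`` optionally records the numeric relative variation a
    sign was derived from, for traceability and exact file round-trips.
    """

    signs: Mapping[str, Sign]
    provenance: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "signs", dict(self.signs))
        object.__setattr__(self, "provenance", dict(self.provenance))
        for node, value in self.provenance.items():
            if value != 0 and node in self.signs:
                if Sign.from_int(1 if value > 0 else -1) is not self.signs[node]:
                    raise GraphValidationError(
                        f"observation for {node!r} disagrees with its numeric value"
                    )

    def __contains__(self, node: str) -> bool:
        return node in self.signs

    def __iter__(self) -> Iterator[str]:
        return iter(self.signs)

    def __len__(self) -> int:
        return len(self.signs)


@dataclass(frozen=True)
class Instance:
    """An influence graph together with an experimental profile."""

    graph: InfluenceGraph
    observations: ObservationSet

    def __post_init__(self) -> None:
        stray = set(self.observations.signs) - self.graph.nodes
        if stray:
            raise GraphValidationError(
                f"observed nodes not in the graph: {sorted(stray)}"
            )


@dataclass(frozen=True)
class TotalLabeling:
    """A total assignment of signs to every node and every edge."""

    node_signs: Mapping[str, Sign]
    edge_signs: Mapping[Edge, Sign]

    def __post_init__(self) -> None:
        object.__setattr__(self, "node_signs", dict(self.node_signs))
        object.__setattr__(self, "edge_signs", dict(self.edge_signs))


def free_variables(instance: Instance) -> tuple[list[str], list[Edge]]:
    """Unobserved nodes and UNKNOWN-labelled edges, lexicographically sorted."""
    free_nodes = sorted(instance.graph.nodes - set(instance.observations.signs))
    free_edges = sorted(
        e for e, lab in instance.graph.edge_labels.items() if lab is EdgeLabel.UNKNOWN
    )
    return free_nodes, free_edges


def satisfies(labeling: TotalLabeling, instance: Instance) -> bool:
    """Does a total labeling satisfy the sign consistency rule on ``instance``?

    True iff the labeling (a) agrees with every observation, (b) agrees
    with every fixed edge label, and (c) at every node outside
    :func:`effective_inputs` at least one incoming edge explains the
    node: source sign times edge sign equals the node's sign.

    Raises :class:`LabelingError` if the labeling misses a node or edge.
    """
    graph = instance.graph
    missing_nodes = graph.nodes - set(labeling.node_signs)
    if missing_nodes:
        raise LabelingError(f"labeling misses nodes {sorted(missing_nodes)}")
    missing_edges = set(graph.edge_labels) - set(labeling.edge_signs)
    if missing_edges:
        raise LabelingError(f"labeling misses edges {sorted(missing_edges)}")

    for node, sign in instance.observations.signs.items():
        if labeling.node_signs[node] is not sign:
            return False
    for edge, lab in graph.edge_labels.items():
        fixed = lab.sign
        if fixed is not None and labeling.edge_signs[edge] is not fixed:
            return False

    exempt = effective_inputs(graph)
    incoming: dict[str, list[Edge]] = {}
    for edge in graph.edge_labels:
        incoming.setdefault(edge[1], []).append(edge)
    for node in graph.nodes:
        if node in exempt:
            continue
        target_sign = labeling.node_signs[node]
        explained = any(
            sign_product(labeling.node_signs[u], labeling.edge_signs[(u, node)])
            is target_sign
            for (u, _) in incoming.get(node, ())
        )
        if not explained:
            return False
    return True
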