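"""Consistency checking, model enumeration and cautious prediction.

An instance (graph + partial observations) is *consistent* when at least
one total labeling of nodes and edges satisfies the explanation rule at
every non-input node while agreeing with all observations and all fixed
edge labels.  Predictions are cautious consequences: the signs carried
by a free variable in *every* consistent labeling, i.e. the intersection
of all solutions.

The decision procedure is a complete backtracking search
(:mod:`signcons._solve`).  Cautious reasoning is implemented with two
satisfiability queries per free variable instead of full enumeration:
``v`` is predicted to be ``s`` exactly when fixing ``v = -s`` makes the
instance infeasible.  Witnesses returned by intermediate queries are
cached to skip queries whose answer they already settle.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

from . import _solve
from .model import (
    Edge,
    Instance,
    Sign,
    SignConsError,
    TotalLabeling,
    free_variables,
)

__all__ = [
    "SolveResult",
    "PredictionTable",
    "LabelingEnumeration",
    "InconsistentInstanceError",
    "EnumerationCapError",
    "solve",
    "enumerate_labelings",
    "predict",
    "possible_signs",
]

#: hard ceiling on 2**(free variables) for uncapped enumeration
ENUMERATION_CAP = 2**20


class InconsistentInstanceError(SignConsError):
    """Prediction was requested on an inconsistent instance.

    Predictions are only defined for consistent instances; repair the
    instance first (see :mod:`signcons.repair`) and use predictions
    under repair.
    """


class EnumerationCapError(SignConsError):
    """The labeling space is too large to enumerate without a limit."""


@dataclass(frozen=True)
class SolveResult:
    consistent: bool
    witness: TotalLabeling | None
    free_variable_count: int


@dataclass(frozen=True)
class LabelingEnumeration:
    labelings: list[TotalLabeling]
    truncated: bool

    def __iter__(self):
        return iter(self.labelings)

    def __len__(self) -> int:
        return len(self.labelings)


@dataclass(frozen=True)
class PredictionTable:
    """Signs forced in every consistent labeling.

    ``scope`` is ``"consistent"`` for plain cautious predictions and
    ``"under_repair"`` when the intersection additionally ranges over
    every minimally repaired instance.  ``repaired_nodes`` /
    ``repaired_edges`` flag variables whose observation or label was
    modified by at least one minimal repair set (only populated in the
    under-repair scope).
    """

    node_predictions: Mapping[str, Sign]
    edge_predictions: Mapping[Edge, Sign]
    scope: str = "consistent"
    repaired_nodes: frozenset[str] = frozenset()
    repaired_edges: frozenset[Edge] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        object.__setattr__(self, "node_predictions", dict(self.node_predictions))
        object.__setattr__(self, "edge_predictions", dict(self.edge_predictions))


def solve(instance: Instance) -> SolveResult:
    """Decide consistency; on success return a deterministic witness."""
    compiled = _solve.CompiledInstance(instance)
    res = _solve.search(compiled, limit=1)
    if res.solutions:
        return SolveResult(True, compiled.labeling(res.solutions[0]),
                           compiled.free_variable_count)
    return SolveResult(False, None, compiled.free_variable_count)


def enumerate_labelings(
    instance: Instance, limit: int | None = None
) -> LabelingEnumeration:
    """All consistent total labelings, in lexicographic order.

    Ordering is over the free-variable vector (unobserved nodes sorted
    lexicographically, then UNKNOWN edges), with ``+`` before ``-``.
    Without ``limit`` the request is refused when the labeling space
    exceeds ``ENUMERATION_CAP``; pass an explicit limit to truncate.
    """
    compiled = _solve.CompiledInstance(instance)
    if limit is None:
        if 2 ** compiled.free_variable_count > ENUMERATION_CAP:
            raise EnumerationCapError(
                f"2**{compiled.free_variable_count} candidate labelings exceed "
                f"the cap of {ENUMERATION_CAP}; pass limit= to truncate"
            )
        res = _solve.search(compiled, limit=ENUMERATION_CAP + 1)
        return LabelingEnumeration(
            [compiled.labeling(s) for s in res.solutions], truncated=False
        )
    if limit <= 0:
        raise ValueError("limit must be positive")
    res = _solve.search(compiled, limit=limit + 1)
    sols = res.solutions[:limit]
    return LabelingEnumeration(
        [compiled.labeling(s) for s in sols],
        truncated=len(res.solutions) > limit,
    )


def possible_signs(
    instance: Instance,
) -> tuple[dict[str, set[Sign]], dict[Edge, set[Sign]], TotalLabeling]:
    """Achievable sign sets for every free variable of a consistent instance.

    Returns ``(node_sets, edge_sets, witness)`` where each set contains
    the signs the variable takes across all consistent labelings (always
    nonempty; a singleton means the variable is forced).  Raises
    :class:`InconsistentInstanceError` when no labeling exists.
    """
    compiled = _solve.CompiledInstance(instance)
    first = _solve.search(compiled, limit=1)
    if not first.solutions:
        raise InconsistentInstanceError(
            "instance admits no consistent labeling; compute repairs instead"
        )
    free_nodes, free_edges = free_variables(instance)

    node_seen: dict[str, set[int]] = {v: set() for v in free_nodes}
    edge_seen: dict[Edge, set[int]] = {e: set() for e in free_edges}

    def record(sol) -> None:
        ns, es = sol
        for v in free_nodes:
            node_seen[v].add(ns[compiled.node_index[v]])
        for e in free_edges:
            edge_seen[e].add(es[compiled.edge_index[e]])

    record(first.solutions[0])
    for v in free_nodes:
        if len(node_seen[v]) == 2:
            continue
        (have,) = node_seen[v]
        probe = _solve.search(
            compiled, assumptions=((_solve._NODE, compiled.node_index[v], -have),)
        )
        if probe.solutions:
            record(probe.solutions[0])
    for e in free_edges:
        if len(edge_seen[e]) == 2:
            continue
        (have,) = edge_seen[e]
        probe = _solve.search(
            compiled, assumptions=((_solve._EDGE, compiled.edge_index[e], -have),)
        )
        if probe.solutions:
            record(probe.solutions[0])

    node_sets = {v: {Sign(x) for x in s} for v, s in node_seen.items()}
    edge_sets = {e: {Sign(x) for x in s} for e, s in edge_seen.items()}
    return node_sets, edge_sets, compiled.labeling(first.solutions[0])


def predict(instance: Instance, include_edges: bool = True) -> PredictionTable:
    """Cautious predictions for a consistent instance.

    A free node (or UNKNOWN edge, unless ``include_edges=False``) is
    assigned a predicted sign exactly when it carries that sign in every
    consistent labeling — equivalently, when fixing the opposite sign
    makes the instance infeasible.
    """
    node_sets, edge_sets, _ = possible_signs(instance)
    node_predictions = {
        v: next(iter(s)) for v, s in node_sets.items() if len(s) == 1
    }
    edge_predictions = (
        {e: next(iter(s)) for e, s in edge_sets.items() if len(s) == 1}
        if include_edges
        else {}
    )
    return PredictionTable(node_predictions, edge_predictions, scope="consistent")
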