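"""Cardinality-minimal repair of inconsistent instances.

When observations contradict the network, consistency can be restored by
small modifications.  Four repair modes are supported, each contributing
atomic modifications ("repair atoms"):

``obs``
    flip the observed sign of a node;
``input``
    declare a node an input, exempting it from the explanation rule;
``edge``
    flip the sign of a fixed (non-``?``) edge;
``add``
    add a new signed edge between existing nodes.

A repair set is a slot-disjoint set of atoms whose application makes the
instance consistent.  :func:`minimal_repairs` enumerates *all* repair
sets of the smallest cardinality (every atom costs 1, also across
modes), the atoms common to all of them, and the cautious predictions
that hold in every consistent labeling of every minimally repaired
instance.

Search is iterative deepening over the atom universe.  Without the
``add`` mode, atoms act within a weakly connected component, so the
instance is decomposed and per-component optima are combined; with
``add`` the search is global.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations, product
from typing import Iterable, Sequence

import networkx as nx

from . import engine
from .model import (
    Edge,
    EdgeLabel,
    Instance,
    InfluenceGraph,
    ObservationSet,
    Sign,
    SignConsError,
    effective_inputs,
    free_variables,
)

__all__ = [
    "RepairAtom",
    "RepairSet",
    "RepairReport",
    "RepairError",
    "MODES",
    "candidate_atoms",
    "apply_repair",
    "minimal_repairs",
    "common_repairs",
    "predict_under_repair",
]

MODES = ("obs", "input", "edge", "add")
DEFAULT_MAX_REPAIR_SIZE = 8

_KIND_ORDER = {"flip_obs": 0, "make_input": 1, "flip_edge": 2, "add_edge": 3}


class RepairError(SignConsError):
    """A repair atom is not applicable to the instance."""


@dataclass(frozen=True)
class RepairAtom:
    """One admissible modification of an instance."""

    kind: str  # flip_obs | make_input | flip_edge | add_edge
    node: str | None = None
    edge: Edge | None = None
    sign: Sign | None = None

    def slot(self) -> tuple:
        """The observation/edge/input slot this atom occupies; two atoms
        in one repair set may not share a slot."""
        if self.kind == "flip_obs":
            return ("obs", self.node)
        if self.kind == "make_input":
            return ("input", self.node)
        return ("edge", self.edge)

    def sort_key(self) -> tuple:
        return (
            _KIND_ORDER[self.kind],
            self.node or "",
            self.edge or ("", ""),
            "" if self.sign is None else self.sign.token,
        )

    def to_line(self) -> str:
        if self.kind in ("flip_obs", "make_input"):
            return f"{self.kind}\t{self.node}"
        if self.kind == "flip_edge":
            return f"flip_edge\t{self.edge[0]}\t{self.edge[1]}"
        return f"add_edge\t{self.edge[0]}\t{self.edge[1]}\t{self.sign.token}"

    @classmethod
    def from_line(cls, line: str) -> "RepairAtom":
        parts = line.rstrip("\n").split("\t")
        kind = parts[0]
        if kind in ("flip_obs", "make_input") and len(parts) == 2:
            return cls(kind, node=parts[1])
        if kind == "flip_edge" and len(parts) == 3:
            return cls(kind, edge=(parts[1], parts[2]))
        if kind == "add_edge" and len(parts) == 4 and parts[3] in ("+", "-"):
            sign = Sign.PLUS if parts[3] == "+" else Sign.MINUS
            return cls(kind, edge=(parts[1], parts[2]), sign=sign)
        raise RepairError(f"malformed repair atom line: {line!r}")

    def __repr__(self) -> str:
        return f"RepairAtom({self.to_line().replace(chr(9), ' ')})"


@dataclass(frozen=True)
class RepairSet:
    atoms: frozenset[RepairAtom]

    def __post_init__(self) -> None:
        object.__setattr__(self, "atoms", frozenset(self.atoms))
        slots = [a.slot() for a in self.atoms]
        if len(set(slots)) != len(slots):
            raise RepairError("repair set contains atoms sharing a slot")

    def __len__(self) -> int:
        return len(self.atoms)

    def __iter__(self):
        return iter(self.atoms)

    def sorted_atoms(self) -> list[RepairAtom]:
        return sorted(self.atoms, key=RepairAtom.sort_key)

    def serialize(self) -> str:
        return "".join(a.to_line() + "\n" for a in self.sorted_atoms())


@dataclass(frozen=True)
class RepairReport:
    """Outcome of minimal-repair enumeration.

    ``minimal_cardinality`` is None when no repair of admissible size
    exists; a consistent instance yields cardinality 0 with one empty
    repair set.
    """

    minimal_cardinality: int | None
    repair_sets: Sequence[RepairSet]
    common: frozenset[RepairAtom]
    predictions_under_repair: engine.PredictionTable | None

    @property
    def found(self) -> bool:
        return self.minimal_cardinality is not None


def _normalize_modes(modes: Iterable[str]) -> tuple[str, ...]:
    modes = tuple(dict.fromkeys(modes))
    if not modes:
        raise ValueError(f"at least one repair mode required, from {MODES}")
    unknown = [m for m in modes if m not in MODES]
    if unknown:
        raise ValueError(f"unknown repair modes {unknown}; valid: {MODES}")
    return modes


def candidate_atoms(
    instance: Instance,
    modes: Iterable[str],
    add_candidates: Iterable[Edge] | None = None,
) -> list[RepairAtom]:
    """The canonically ordered atom universe for the selected modes.

    ``add`` candidates range over all ordered pairs with no existing
    edge, distinct endpoints and a non-input target, both signs per
    pair; ``add_candidates`` restricts them to a user-supplied list of
    hypothesised pairs.
    """
    modes = _normalize_modes(modes)
    graph = instance.graph
    inputs = effective_inputs(graph)
    atoms: list[RepairAtom] = []
    if "obs" in modes:
        atoms += [
            RepairAtom("flip_obs", node=v)
            for v in sorted(instance.observations.signs)
        ]
    if "input" in modes:
        atoms += [
            RepairAtom("make_input", node=v)
            for v in graph.sorted_nodes()
            if v not in inputs
        ]
    if "edge" in modes:
        atoms += [
            RepairAtom("flip_edge", edge=e)
            for e in graph.sorted_edges()
            if graph.edge_labels[e] is not EdgeLabel.UNKNOWN
        ]
    if "add" in modes:
        if add_candidates is None:
            pairs = (
                (u, v)
                for u in graph.sorted_nodes()
                for v in graph.sorted_nodes()
            )
        else:
            pairs = iter(sorted(set(add_candidates)))
        for (u, v) in pairs:
            if u == v or (u, v) in graph.edge_labels or v in inputs:
                continue
            if u not in graph.nodes or v not in graph.nodes:
                raise RepairError(f"add-edge candidate ({u!r}, {v!r}) not in graph")
            for sign in (Sign.PLUS, Sign.MINUS):
                atoms.append(RepairAtom("add_edge", edge=(u, v), sign=sign))
    return atoms


def apply_repair(instance: Instance, repair: RepairSet | Iterable[RepairAtom]) -> Instance:
    """A new instance with the repair applied; the original is untouched."""
    if not isinstance(repair, RepairSet):
        repair = RepairSet(frozenset(repair))
    graph = instance.graph
    inputs = effective_inputs(graph)
    signs = dict(instance.observations.signs)
    provenance = {
        v: x for v, x in instance.observations.provenance.items()
    }
    edge_labels = dict(graph.edge_labels)
    declared = set(graph.declared_inputs)
    for atom in repair.sorted_atoms():
        if atom.kind == "flip_obs":
            if atom.node not in signs:
                raise RepairError(f"flip_obs targets unobserved node {atom.node!r}")
            signs[atom.node] = -signs[atom.node]
            provenance.pop(atom.node, None)
        elif atom.kind == "make_input":
            if atom.node not in graph.nodes:
                raise RepairError(f"make_input targets unknown node {atom.node!r}")
            if atom.node in inputs:
                raise RepairError(f"make_input targets input node {atom.node!r}")
            declared.add(atom.node)
        elif atom.kind == "flip_edge":
            lab = edge_labels.get(atom.edge)
            if lab is None:
                raise RepairError(f"flip_edge targets missing edge {atom.edge}")
            if lab is EdgeLabel.UNKNOWN:
                raise RepairError(
                    f"flip_edge targets unknown-labelled edge {atom.edge}"
                )
            edge_labels[atom.edge] = (
                EdgeLabel.MINUS if lab is EdgeLabel.PLUS else EdgeLabel.PLUS
            )
        else:  # add_edge
            u, v = atom.edge
            if (u, v) in graph.edge_labels:
                raise RepairError(f"add_edge targets existing edge {atom.edge}")
            if u == v:
                raise RepairError("add_edge may not create a self-loop")
            if v in inputs:
                raise RepairError(f"add_edge targets input node {v!r}")
            if u not in graph.nodes or v not in graph.nodes:
                raise RepairError(f"add_edge endpoints not in graph: {atom.edge}")
            edge_labels[(u, v)] = EdgeLabel.from_sign(atom.sign)
    new_graph = InfluenceGraph(graph.nodes, edge_labels, frozenset(declared))
    return Instance(new_graph, ObservationSet(signs, provenance))


def common_repairs(report: RepairReport) -> frozenset[RepairAtom]:
    """Atoms present in every minimal repair set."""
    if not report.repair_sets:
        raise ValueError("report contains no repair sets")
    common = set(report.repair_sets[0].atoms)
    for rs in report.repair_sets[1:]:
        common &= rs.atoms
    return frozenset(common)


# ---------------------------------------------------------------------------
# minimal-repair search


def _components(instance: Instance) -> list[Instance]:
    g = nx.DiGraph()
    g.add_nodes_from(instance.graph.nodes)
    g.add_edges_from(instance.graph.edge_labels)
    parts = []
    for comp in nx.weakly_connected_components(g):
        sub_graph = InfluenceGraph(
            nodes=frozenset(comp),
            edge_labels={
                e: lab
                for e, lab in instance.graph.edge_labels.items()
                if e[0] in comp
            },
            declared_inputs=instance.graph.declared_inputs & comp,
        )
        sub_obs = ObservationSet(
            signs={
                v: s
                for v, s in instance.observations.signs.items()
                if v in comp
            }
        )
        parts.append(Instance(sub_graph, sub_obs))
    parts.sort(key=lambda inst: min(inst.graph.nodes))
    return parts


def _admissible_sets_at(
    instance: Instance, universe: Sequence[RepairAtom], k: int
) -> list[RepairSet]:
    """All slot-disjoint k-subsets of ``universe`` that repair ``instance``."""
    out = []
    for combo in combinations(universe, k):
        slots = {a.slot() for a in combo}
        if len(slots) != k:
            continue
        candidate = RepairSet(frozenset(combo))
        if engine.solve(apply_repair(instance, candidate)).consistent:
            out.append(candidate)
    return out


def _deepening(
    instance: Instance, universe: Sequence[RepairAtom], max_size: int
) -> tuple[int | None, list[RepairSet]]:
    if engine.solve(instance).consistent:
        return 0, [RepairSet(frozenset())]
    for k in range(1, max_size + 1):
        found = _admissible_sets_at(instance, universe, k)
        if found:
            return k, found
    return None, []


def minimal_repairs(
    instance: Instance,
    modes: Iterable[str],
    max_size: int = DEFAULT_MAX_REPAIR_SIZE,
    add_candidates: Iterable[Edge] | None = None,
    with_predictions: bool = True,
) -> RepairReport:
    """All repair sets of minimal cardinality, their intersection, and
    (optionally) predictions under repair.

    Iterative deepening over k = 0, 1, ... ≤ ``max_size``: at the first
    cardinality admitting a repair, every admissible set of that size is
    returned.  A consistent instance yields cardinality 0 with a single
    empty repair set.  When no repair exists within ``max_size`` the
    report has ``found == False`` (not an error).
    """
    modes = _normalize_modes(modes)
    if max_size < 0:
        raise ValueError("max_size must be nonnegative")

    if "add" in modes:
        universe = candidate_atoms(instance, modes, add_candidates)
        k, sets = _deepening(instance, universe, max_size)
    else:
        # atoms act within a weakly connected component: solve each
        # component independently and combine the per-component optima
        k_total = 0
        per_comp: list[list[RepairSet]] = []
        k = 0
        for comp in _components(instance):
            comp_universe = candidate_atoms(comp, modes)
            comp_k, comp_sets = _deepening(comp, comp_universe, max_size - k_total)
            if comp_k is None:
                k = None
                break
            k_total += comp_k
            if comp_k > 0:
                per_comp.append(comp_sets)
        if k is None:
            sets = []
        else:
            k = k_total
            sets = [
                RepairSet(frozenset().union(*(rs.atoms for rs in choice)))
                for choice in product(*per_comp)
            ] if per_comp else [RepairSet(frozenset())]

    sets = sorted(sets, key=RepairSet.serialize)
    if k is None:
        return RepairReport(None, [], frozenset(), None)
    report = RepairReport(
        k,
        sets,
        frozenset.intersection(*(frozenset(rs.atoms) for rs in sets)),
        None,
    )
    if with_predictions:
        table = predict_under_repair(instance, report)
        report = RepairReport(k, sets, report.common, table)
    return report


def predict_under_repair(
    instance: Instance,
    report: RepairReport | Sequence[RepairSet],
    include_edges: bool = True,
) -> engine.PredictionTable:
    """Signs holding in every labeling of every minimally repaired instance.

    The candidate variables are the free variables of the original
    instance plus every observation or fixed edge flipped by at least
    one repair set (in the repaired instances where they are untouched
    they contribute their fixed sign).  A variable is predicted when the
    union of its achievable signs across all repaired instances is a
    singleton.
    """
    repair_sets = report.repair_sets if isinstance(report, RepairReport) else report
    if not repair_sets:
        raise ValueError("predictions under repair require at least one repair set")

    free_nodes, free_edges = free_variables(instance)
    flipped_nodes = frozenset(
        a.node for rs in repair_sets for a in rs.atoms if a.kind == "flip_obs"
    )
    flipped_edges = frozenset(
        a.edge for rs in repair_sets for a in rs.atoms if a.kind == "flip_edge"
    )
    node_candidates = sorted(set(free_nodes) | flipped_nodes)
    edge_candidates = sorted(set(free_edges) | flipped_edges)

    node_union: dict[str, set[Sign]] = {v: set() for v in node_candidates}
    edge_union: dict[Edge, set[Sign]] = {e: set() for e in edge_candidates}
    for rs in repair_sets:
        repaired = apply_repair(instance, rs)
        node_sets, edge_sets, _ = engine.possible_signs(repaired)
        for v in node_candidates:
            obs = repaired.observations.signs.get(v)
            node_union[v] |= node_sets.get(v, {obs} if obs else set())
        for e in edge_candidates:
            lab = repaired.graph.edge_labels[e].sign
            edge_union[e] |= edge_sets.get(e, {lab} if lab else set())

    node_predictions = {
        v: next(iter(s)) for v, s in node_union.items() if len(s) == 1
    }
    edge_predictions = (
        {e: next(iter(s)) for e, s in edge_union.items() if len(s) == 1}
        if include_edges
        else {}
    )
    return engine.PredictionTable(
        node_predictions,
        edge_predictions,
        scope="under_repair",
        repaired_nodes=flipped_nodes,
        repaired_edges=flipped_edges,
    )
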