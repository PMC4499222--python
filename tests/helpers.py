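"""Small builders shared by the tests."""

from __future__ import annotations

from signcons.model import (
    EdgeLabel,
    Instance,
    InfluenceGraph,
    ObservationSet,
    Sign,
)

_LABELS = {"+": EdgeLabel.PLUS, "-": EdgeLabel.MINUS, "?": EdgeLabel.UNKNOWN}
_SIGNS = {"+": Sign.PLUS, "-": Sign.MINUS}


def graph(*edges: tuple[str, str, str], nodes=(), inputs=()) -> InfluenceGraph:
    """Build a graph from ``(source, sign, target)`` triples.

    ``nodes`` adds isolated nodes; ``inputs`` declares input nodes.
    """
    edge_labels = {(u, v): _LABELS[s] for (u, s, v) in edges}
    all_nodes = set(nodes) | set(inputs)
    for (u, v) in edge_labels:
        all_nodes.update((u, v))
    return InfluenceGraph(frozenset(all_nodes), edge_labels, frozenset(inputs))


def obs(**signs: str) -> ObservationSet:
    return ObservationSet({v: _SIGNS[s] for v, s in signs.items()})


def inst(*edges, nodes=(), inputs=(), **signs) -> Instance:
    return Instance(graph(*edges, nodes=nodes, inputs=inputs), obs(**signs))


# ---------------------------------------------------------------------------
# hypothesis strategy for random small instances

from hypothesis import strategies as st  # noqa: E402


@st.composite
def small_instances(draw, max_nodes: int = 4, max_edges: int = 6):
    n = draw(st.integers(min_value=1, max_value=max_nodes))
    names = [f"N{i}" for i in range(n)]
    pairs = [(u, v) for u in names for v in names]
    edges = draw(
        st.lists(st.sampled_from(pairs), max_size=min(max_edges, len(pairs)),
                 unique=True)
    )
    labels = {
        e: draw(st.sampled_from(list(_LABELS.values()))) for e in edges
    }
    declared = frozenset(
        draw(st.lists(st.sampled_from(names), unique=True, max_size=n))
    )
    observed = {
        v: draw(st.sampled_from(list(_SIGNS.values())))
        for v in names
        if draw(st.booleans())
    }
    g = InfluenceGraph(frozenset(names), labels, declared)
    return Instance(g, ObservationSet(observed))
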