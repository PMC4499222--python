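"""Random influence-graph instances with planted consistent labelings.

The generator emulates a steady-state shift experiment over a regulatory
network: a random digraph (uniform Erdős–Rényi over ordered pairs,
no self-loops), a hidden total labeling of node variations and edge
signs constructed so the sign-consistency rule holds everywhere, and a
partial observation of the node variations.  Inconsistency is created
on demand by :func:`perturb_observations`, which negates a chosen number
of observed signs — mimicking unreliable measurements.

Generation is a pure function of the configuration: the same seed
always produces byte-identical instances.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, replace

from .model import (
    EdgeLabel,
    Instance,
    InfluenceGraph,
    ObservationSet,
    Sign,
    TotalLabeling,
    effective_inputs,
    satisfies,
    sign_product,
)

__all__ = [
    "GeneratorConfig",
    "PlantedTruth",
    "generate_consistent_instance",
    "perturb_observations",
]


@dataclass(frozen=True)
class GeneratorConfig:
    """Study-design knobs for synthetic instances.

    Defaults model a mid-size regulatory subnetwork: 30 genes with a
    mean in-degree around two (the edge/node ratio typical of curated
    transcriptional networks), a tenth of the genes experimentally
    clamped as inputs, half of the variations measured, and a small
    fraction of regulations of unknown mode.
    """

    n_nodes: int = 30
    edge_density: float = 0.07
    input_fraction: float = 0.1
    obs_fraction: float = 0.5
    unknown_edge_fraction: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_nodes <= 0:
            raise ValueError("n_nodes must be positive")
        for name in ("edge_density", "input_fraction", "obs_fraction",
                     "unknown_edge_fraction"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {value}")


@dataclass(frozen=True)
class PlantedTruth:
    """The hidden labeling an instance was built from, plus any injected
    observation flips (empty until :func:`perturb_observations`)."""

    labeling: TotalLabeling
    injected_flips: frozenset[str] = frozenset()


def _node_name(i: int, width: int) -> str:
    return f"G{i:0{width}d}"


def generate_consistent_instance(
    config: GeneratorConfig,
) -> tuple[Instance, PlantedTruth]:
    """A random instance that is consistent by construction.

    Node signs are sampled uniformly; every non-input node gets one of
    its incoming edges re-signed so that it explains the planted sign,
    making the planted labeling a witness.  A fraction of edges is then
    relabelled ``?`` and a fraction of node signs published as
    observations.
    """
    rng = random.Random(config.seed)
    width = max(3, len(str(config.n_nodes)))
    nodes = [_node_name(i + 1, width) for i in range(config.n_nodes)]

    edges = [
        (u, v)
        for u in nodes
        for v in nodes
        if u != v and rng.random() < config.edge_density
    ]
    declared = frozenset(v for v in nodes if rng.random() < config.input_fraction)

    planted_nodes = {v: rng.choice((Sign.PLUS, Sign.MINUS)) for v in nodes}
    planted_edges = {
        e: rng.choice((Sign.PLUS, Sign.MINUS)) for e in edges
    }

    graph_skeleton = InfluenceGraph(
        frozenset(nodes),
        {e: EdgeLabel.PLUS for e in edges},
        declared,
    )
    incoming: dict[str, list[tuple[str, str]]] = {v: [] for v in nodes}
    for (u, v) in edges:
        incoming[v].append((u, v))
    exempt = effective_inputs(graph_skeleton)
    for v in nodes:
        if v in exempt:
            continue
        support = rng.choice(sorted(incoming[v]))
        # source * edge must equal the planted target sign
        planted_edges[support] = sign_product(
            planted_nodes[support[0]], planted_nodes[v]
        )

    labels = {e: EdgeLabel.from_sign(planted_edges[e]) for e in edges}
    for e in sorted(edges):
        if rng.random() < config.unknown_edge_fraction:
            labels[e] = EdgeLabel.UNKNOWN

    observed = {
        v: planted_nodes[v] for v in nodes if rng.random() < config.obs_fraction
    }

    graph = InfluenceGraph(frozenset(nodes), labels, declared)
    instance = Instance(graph, ObservationSet(observed))
    truth = PlantedTruth(TotalLabeling(planted_nodes, planted_edges))
    assert satisfies(truth.labeling, instance)
    return instance, truth


def perturb_observations(
    instance: Instance, truth: PlantedTruth, m: int, seed: int
) -> tuple[Instance, PlantedTruth]:
    """Negate the observed signs of ``m`` distinct nodes.

    Models corrupted measurements; the flipped nodes are recorded in the
    returned truth so tests can verify that undoing them (or a repair of
    no larger cardinality) restores consistency.
    """
    observed = sorted(instance.observations.signs)
    if m < 0 or m > len(observed):
        raise ValueError(
            f"cannot flip {m} of {len(observed)} observed nodes"
        )
    rng = random.Random(seed)
    flips = frozenset(rng.sample(observed, m))
    signs = {
        v: (-s if v in flips else s)
        for v, s in instance.observations.signs.items()
    }
    perturbed = Instance(instance.graph, ObservationSet(signs))
    return perturbed, replace(truth, injected_flips=flips)
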