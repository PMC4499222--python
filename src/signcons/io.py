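"""Readers and writers for the two-text-file protocol and result exports.

The interchange formats are deliberately minimal, line-oriented text:

* **network file** — one interaction per line, tab-separated
  ``source  sign  target`` where the sign token is ``+``/``-``/``?``
  (synonyms configurable through :class:`DialectConfig`); a line with a
  single identifier declares a node without interactions;
* **observation file** — ``node  value`` per line, where the value is a
  sign token or a signed decimal relative variation (its arithmetic sign
  is used; magnitudes at or below ``min_abs`` are treated as
  unobserved);
* **inputs file** — one node identifier per line;
* result files — ``predictions.tsv``, ``mics.tsv``, ``repair_NNN.txt``,
  ``common_repairs.txt`` and RFC-4180 node/edge attribute CSVs that can
  be imported into Cytoscape 3 as table columns for styling.

All writers emit canonically ordered, byte-reproducible output.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from .engine import PredictionTable
from .mic import MIC
from .model import (
    Edge,
    EdgeLabel,
    InfluenceGraph,
    Instance,
    ObservationSet,
    Sign,
    SignConsError,
)
from .repair import RepairAtom, RepairSet

__all__ = [
    "DialectConfig",
    "ColorScheme",
    "ParseError",
    "read_network",
    "write_network",
    "write_inputs",
    "read_observations",
    "write_observations",
    "write_repair_sets",
    "read_repair_set",
    "write_common_repairs",
    "write_predictions",
    "read_predictions",
    "write_edge_predictions",
    "read_edge_predictions",
    "write_mics",
    "export_attribute_tables",
]

logger = logging.getLogger("signcons")


class ParseError(SignConsError):
    """A file could not be parsed; the message carries the line number."""


_DEFAULT_TOKENS = {
    "+": EdgeLabel.PLUS,
    "1": EdgeLabel.PLUS,
    "activation": EdgeLabel.PLUS,
    "-": EdgeLabel.MINUS,
    "-1": EdgeLabel.MINUS,
    "inhibition": EdgeLabel.MINUS,
    "?": EdgeLabel.UNKNOWN,
    "unknown": EdgeLabel.UNKNOWN,
}


@dataclass(frozen=True)
class DialectConfig:
    sign_token_map: dict[str, EdgeLabel] = field(
        default_factory=lambda: dict(_DEFAULT_TOKENS)
    )
    comment_prefix: str = "#"
    delimiter: str = "\t"

    def __post_init__(self) -> None:
        lowered: dict[str, EdgeLabel] = {}
        for token, label in self.sign_token_map.items():
            key = token.lower()
            if lowered.get(key, label) is not label:
                raise ValueError(f"sign token {token!r} maps to two labels")
            lowered[key] = label
        object.__setattr__(self, "sign_token_map", lowered)


@dataclass(frozen=True)
class ColorScheme:
    """Colour conventions for the attribute exports: cyan marks
    up-regulation and yellow down-regulation; predictions are rendered
    as border colours, observations as fill colours."""

    up_color: str = "cyan"
    down_color: str = "yellow"
    prediction_marker: str = "border"
    common_repair_marker: str = "alternating"

    def color_for(self, sign: Sign) -> str:
        return self.up_color if sign is Sign.PLUS else self.down_color


def _data_lines(path: Path, dialect: DialectConfig) -> Iterable[tuple[int, str]]:
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(dialect.comment_prefix):
                continue
            yield lineno, line


def read_network(
    path: str | Path,
    dialect: DialectConfig | None = None,
    inputs_path: str | Path | None = None,
) -> InfluenceGraph:
    """Parse a SIF-style ``source  sign  target`` file.

    Identical duplicate lines are deduplicated with a warning;
    duplicates with conflicting signs are an error.  The optional inputs
    file declares input nodes, one per line; each must appear in the
    network.
    """
    path = Path(path)
    dialect = dialect or DialectConfig()
    nodes: set[str] = set()
    edge_labels: dict[Edge, EdgeLabel] = {}
    for lineno, line in _data_lines(path, dialect):
        parts = [p.strip() for p in line.split(dialect.delimiter)]
        if len(parts) == 1 and parts[0]:
            # a bare identifier declares a node without interactions, so
            # isolated nodes survive a write/read cycle
            nodes.add(parts[0])
            continue
        if len(parts) != 3 or not all(parts):
            raise ParseError(
                f"{path}:{lineno}: expected 'source{dialect.delimiter}sign"
                f"{dialect.delimiter}target', got {line!r}"
            )
        source, token, target = parts
        label = dialect.sign_token_map.get(token.lower())
        if label is None:
            raise ParseError(f"{path}:{lineno}: unknown sign token {token!r}")
        edge = (source, target)
        if edge in edge_labels:
            if edge_labels[edge] is label:
                logger.warning("%s:%d: duplicate edge %s ignored", path, lineno, edge)
                continue
            raise ParseError(
                f"{path}:{lineno}: conflicting duplicate edge {edge}: "
                f"{edge_labels[edge].value} vs {label.value}"
            )
        edge_labels[edge] = label
        nodes.update(edge)

    declared: set[str] = set()
    if inputs_path is not None:
        for lineno, line in _data_lines(Path(inputs_path), dialect):
            node = line.strip()
            if node not in nodes:
                raise ParseError(
                    f"{inputs_path}:{lineno}: input node {node!r} absent from network"
                )
            declared.add(node)
    return InfluenceGraph(frozenset(nodes), edge_labels, frozenset(declared))


def write_network(graph: InfluenceGraph, path: str | Path) -> None:
    touched = {n for e in graph.edge_labels for n in e}
    with open(path, "w", encoding="utf-8") as fh:
        for (u, v) in graph.sorted_edges():
            fh.write(f"{u}\t{graph.edge_labels[(u, v)].value}\t{v}\n")
        for node in sorted(graph.nodes - touched):
            fh.write(node + "\n")


def write_inputs(graph: InfluenceGraph, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for node in sorted(graph.declared_inputs):
            fh.write(node + "\n")


def read_observations(
    path: str | Path,
    graph: InfluenceGraph,
    dialect: DialectConfig | None = None,
    min_abs: float = 0.0,
) -> ObservationSet:
    """Parse a ``node  value`` observation file.

    Values are ``+``/``-`` tokens or decimal relative variations, whose
    arithmetic sign is taken; magnitudes ≤ ``min_abs`` (default 0, so
    exactly-zero values) leave the node unobserved with a warning.
    """
    path = Path(path)
    dialect = dialect or DialectConfig()
    signs: dict[str, Sign] = {}
    provenance: dict[str, float] = {}
    stray: list[str] = []
    for lineno, line in _data_lines(path, dialect):
        parts = [p.strip() for p in line.split(dialect.delimiter)]
        if len(parts) != 2 or not all(parts):
            raise ParseError(
                f"{path}:{lineno}: expected 'node{dialect.delimiter}value', got {line!r}"
            )
        node, token = parts
        if node not in graph.nodes:
            stray.append(node)
            continue
        label = dialect.sign_token_map.get(token.lower())
        if label in (EdgeLabel.PLUS, EdgeLabel.MINUS):
            sign = label.sign
            value = None
        else:
            try:
                value = float(token)
            except ValueError:
                raise ParseError(
                    f"{path}:{lineno}: expected a sign or a number, got {token!r}"
                ) from None
            if abs(value) <= min_abs:
                logger.warning(
                    "%s:%d: %s has |variation| <= %g; left unobserved",
                    path, lineno, node, min_abs,
                )
                continue
            sign = Sign.from_int(1 if value > 0 else -1)
        if node in signs:
            if signs[node] is sign:
                logger.warning("%s:%d: duplicate observation for %s", path, lineno, node)
                continue
            raise ParseError(
                f"{path}:{lineno}: conflicting duplicate observation for {node!r}"
            )
        signs[node] = sign
        if value is not None:
            provenance[node] = value
    if stray:
        raise ParseError(
            f"{path}: observed nodes absent from the network: {sorted(set(stray))}"
        )
    return ObservationSet(signs, provenance)


def write_observations(obs: ObservationSet, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for node in sorted(obs.signs):
            if node in obs.provenance:
                fh.write(f"{node}\t{obs.provenance[node]!r}\n")
            else:
                fh.write(f"{node}\t{obs.signs[node].token}\n")


# ---------------------------------------------------------------------------
# repair sets


def write_repair_sets(
    repair_sets: Sequence[RepairSet], out_dir: str | Path
) -> list[Path]:
    """One file per repair set (``repair_001.txt`` …) in canonical order.

    Sets are ordered by their serialized form; atoms within a file are
    sorted by kind then identifiers.  Re-running on identical input
    produces byte-identical files.  An empty list writes nothing.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    ordered = sorted(repair_sets, key=RepairSet.serialize)
    width = max(3, len(str(len(ordered))))
    for i, rs in enumerate(ordered, start=1):
        p = out_dir / f"repair_{i:0{width}d}.txt"
        p.write_text(rs.serialize(), encoding="utf-8")
        paths.append(p)
    return paths


def read_repair_set(path: str | Path) -> RepairSet:
    atoms = []
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            if line.strip():
                atoms.append(RepairAtom.from_line(line))
    return RepairSet(frozenset(atoms))


def write_common_repairs(common: Iterable[RepairAtom], path: str | Path) -> None:
    ordered = sorted(common, key=RepairAtom.sort_key)
    with open(path, "w", encoding="utf-8") as fh:
        for atom in ordered:
            fh.write(atom.to_line() + "\n")


# ---------------------------------------------------------------------------
# predictions and MICs

_PRED_HEADER = "node\tsign\tscope"
_EDGE_PRED_HEADER = "source\ttarget\tsign\tscope"


def write_predictions(table: PredictionTable, path: str | Path) -> None:
    """Node predictions, one ``node  sign  scope`` row per node, sorted."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(_PRED_HEADER + "\n")
        for node in sorted(table.node_predictions):
            fh.write(f"{node}\t{table.node_predictions[node].token}\t{table.scope}\n")


def read_predictions(path: str | Path) -> PredictionTable:
    node_predictions: dict[str, Sign] = {}
    scope = "consistent"
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n")
        if header != _PRED_HEADER:
            raise ParseError(f"{path}:1: unexpected header {header!r}")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 3 or parts[1] not in ("+", "-"):
                raise ParseError(f"{path}:{lineno}: malformed prediction row")
            node_predictions[parts[0]] = (
                Sign.PLUS if parts[1] == "+" else Sign.MINUS
            )
            scope = parts[2]
    return PredictionTable(node_predictions, {}, scope=scope)


def write_edge_predictions(table: PredictionTable, path: str | Path) -> None:
    """Predicted signs for ``?``-labelled edges, as a separate table."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(_EDGE_PRED_HEADER + "\n")
        for (u, v) in sorted(table.edge_predictions):
            sign = table.edge_predictions[(u, v)]
            fh.write(f"{u}\t{v}\t{sign.token}\t{table.scope}\n")


def read_edge_predictions(path: str | Path) -> dict[Edge, Sign]:
    out: dict[Edge, Sign] = {}
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n")
        if header != _EDGE_PRED_HEADER:
            raise ParseError(f"{path}:1: unexpected header {header!r}")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 4 or parts[2] not in ("+", "-"):
                raise ParseError(f"{path}:{lineno}: malformed edge prediction row")
            out[(parts[0], parts[1])] = Sign.PLUS if parts[2] == "+" else Sign.MINUS
    return out


def write_mics(mics: Sequence[MIC], path: str | Path) -> None:
    """One MIC per row, member nodes tab-separated, ordered by size then
    lexicographically."""
    ordered = sorted(mics, key=MIC.sort_key)
    with open(path, "w", encoding="utf-8") as fh:
        for m in ordered:
            fh.write("\t".join(sorted(m.members)) + "\n")


# ---------------------------------------------------------------------------
# Cytoscape attribute exports


def export_attribute_tables(
    instance: Instance,
    table: PredictionTable | None,
    common: Iterable[RepairAtom] = (),
    scheme: ColorScheme | None = None,
    out_dir: str | Path = ".",
) -> list[Path]:
    """Node and edge attribute CSVs for Cytoscape 3 table import.

    Observed nodes carry a fill colour, predicted nodes a border colour
    (up = ``up_color``, down = ``down_color``); nodes and edges touched
    by a repair atom common to all minimal repair sets are flagged so a
    visual style can highlight them.
    """
    scheme = scheme or ColorScheme()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    common = set(common)
    common_nodes = {a.node for a in common if a.kind in ("flip_obs", "make_input")}
    common_edges = {a.edge for a in common if a.kind == "flip_edge"}

    node_preds = table.node_predictions if table else {}
    node_path = out_dir / "node_attributes.csv"
    with open(node_path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(
            ["id", "observed_sign", "predicted_sign", "fill_color",
             "border_color", "common_repair_flag"]
        )
        for node in instance.graph.sorted_nodes():
            observed = instance.observations.signs.get(node)
            predicted = node_preds.get(node)
            writer.writerow([
                node,
                observed.token if observed else "",
                predicted.token if predicted else "",
                scheme.color_for(observed) if observed else "",
                scheme.color_for(predicted) if predicted else "",
                "true" if node in common_nodes else "false",
            ])

    edge_path = out_dir / "edge_attributes.csv"
    with open(edge_path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["source", "target", "sign", "flipped_in_all_repairs_flag"])
        for (u, v) in instance.graph.sorted_edges():
            writer.writerow([
                u, v,
                instance.graph.edge_labels[(u, v)].value,
                "true" if (u, v) in common_edges else "false",
            ])
    return [node_path, edge_path]
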