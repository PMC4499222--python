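# signcons

Qualitative reasoning on signed influence graphs: consistency checking,
cautious prediction, minimal inconsistent cores, and minimal network
repair — for regulatory-network analysis with steady-state shift
expression data.

## The problem

A regulatory network can be abstracted as an *influence graph*: a
directed graph whose vertices are genes (or proteins, metabolites) and
whose edges carry a sign — `+` for activation, `-` for inhibition, `?`
when the mode of regulation is unknown. A perturbation experiment
(e.g. a knock-out) yields a partial *observation profile*: the sign of
the variation of some nodes between two steady states (`+` up-regulated,
`-` down-regulated, or a numeric relative variation whose sign is used).

The **sign consistency** rule connects the two: the variation of every
node `v` that is not an input must be *explained* by at least one
predecessor, i.e. there must exist an edge `u → v` with

```
sign(u) · sign(u → v) = sign(v)
```

Input nodes (declared by the user, plus every node with no incoming
edge) are exempt. A graph-plus-profile *instance* is **consistent** when
the partial labelling extends to a total labelling of all nodes and
edges satisfying this rule everywhere required.

From this single rule the package derives:

- **check** — is the instance consistent? (exact decision, with a
  deterministic witness labelling);
- **predict** — *cautious* consequences: signs carried by an unobserved
  node (or `?` edge) in **every** consistent labelling, i.e. the
  intersection of all solutions; `v ↦ s` is emitted exactly when fixing
  `v = ¬s` is infeasible;
- **mic** — *minimal inconsistent cores*: minimal sets of non-input
  nodes whose explanation requirements cannot be met jointly on their
  scope (the members, their predecessors and the edges into members) —
  a concise localisation of what is wrong;
- **repair** — all **cardinality-minimal repair sets** under any
  combination of four repair modes (flip observations, flip influence
  signs, declare nodes as inputs, add influences), the atoms *common*
  to every minimal repair set, and predictions that hold under **all**
  minimally repaired instances.

The decision core is an exact backtracking search with unit-style
propagation over the free sign variables; every reasoning mode is
validated in the test suite against brute-force enumeration on an
exhaustive sweep of small instances.

## Worked example

Generate a 12-gene synthetic instance with a planted consistent
labelling, corrupt one observation, and analyse it:

```sh
signcons generate --n-nodes 12 --seed 1 --perturb 1 --out-dir fixture
signcons check  --network fixture/network.tsv --observations fixture/observations.tsv \
                --inputs fixture/inputs.txt --out-dir out
# network: consistent: false        (exit code 2)

signcons mic    --network fixture/network.tsv --observations fixture/observations.tsv \
                --inputs fixture/inputs.txt --out-dir out
# network: 1 minimal inconsistent cores      -> out/network/mics.tsv: G010

signcons repair --network fixture/network.tsv --observations fixture/observations.tsv \
                --inputs fixture/inputs.txt --repair-modes obs --out-dir out
# network: 2 minimal repair sets of size 1; 0 common atoms
```

The repair run writes one file per minimal repair set plus the
predictions that survive all of them:

```
out/network/repair_001.txt   flip_obs  G002
out/network/repair_002.txt   flip_obs  G010
out/network/predictions.tsv  G007  +  under_repair
```

Reading: the corrupted profile can be reconciled with the network by
flipping a single observed sign, either on `G002` (which is in fact the
observation the generator corrupted — see `fixture/truth.json`) or on
`G010`; no atom is shared by both repair sets, and in every consistent
labelling of both repaired instances the unobserved gene `G007` is
up-regulated, so `G007 = +` is a prediction under repair.

The same analyses are available as library calls (`signcons.solve`,
`signcons.predict`, `signcons.find_mics`, `signcons.minimal_repairs`),
e.g. the classic single-edge motif:

```python
>>> from signcons import *
>>> from signcons.model import EdgeLabel
>>> g = InfluenceGraph({"MET4", "MET16"}, {("MET4", "MET16"): EdgeLabel.PLUS})
>>> predict(Instance(g, ObservationSet({"MET16": Sign.PLUS}))).node_predictions
{'MET4': Sign(+)}
```

An observed up-regulation of `MET16`, positively regulated by `MET4`
alone, forces the up-regulation of `MET4`.

Several `--network/--observations` pairs may be passed at once;
`--jobs N` analyses up to `N` networks concurrently (one worker per
network) with byte-identical outputs regardless of `N`. Node and edge
attribute CSVs written next to each result can be imported into
Cytoscape 3 to colour observations (fill: cyan = up, yellow = down),
predictions (border colour) and common repairs (flag column).

## File formats

Tab-separated text throughout: networks as `source  sign  target` lines
(`+`/`-`/`?`, with `activation`, `inhibition`, `1`, `-1`, `unknown` as
accepted synonyms; a bare identifier declares an isolated node),
observations as `node  value` lines (sign token or decimal variation),
declared inputs one node per line. Results: `predictions.tsv`,
`predictions_edges.tsv`, `mics.tsv`, `repair_NNN.txt`,
`common_repairs.txt`, and RFC-4180 `node_attributes.csv` /
`edge_attributes.csv`. All outputs are canonically ordered and
byte-reproducible.
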