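# Methods

## Model

An *instance* is a signed directed graph `G = (V, E)` with edge labels
in `{+, -, ?}`, a declared input set `I₀ ⊆ V`, and a partial observation
map `µ : V ⇀ {+, -}`. The *effective inputs* are
`I = I₀ ∪ {v : indeg(v) = 0}`; a node without predecessors can never be
explained, so it is exempted automatically (the declared set alone would
make such instances trivially infeasible).

A *total labelling* assigns a sign to every node and every edge. It
satisfies the instance when

1. it agrees with `µ` on every observed node (including observed nodes
   that are inputs — an observation fixes a variable regardless of the
   explanation rule),
2. it agrees with every `+`/`-` edge label (`?` edges are free
   variables, not a third sign), and
3. every node `v ∉ I` is explained by at least one predecessor:
   `∃ (u→v) ∈ E` with `sign(u)·sign(u→v) = sign(v)`.

Consistency, cautious prediction, minimal inconsistent cores and
minimal repairs are all defined on top of this satisfaction predicate,
exactly as in the package README.

## Decision procedure

`signcons._solve` compiles an instance to index arrays and runs
depth-first search over the free variables — unobserved nodes in
lexicographic order, then `?` edges — asserting `+` before `-`, with a
propagation loop between decisions:

- *forced support*: if an assigned node has exactly one undecided
  incoming contribution left and that contribution has a single unknown
  factor, the factor is fixed to the explaining value;
- *forced node*: if all incoming contributions of an unassigned
  non-input node are decided and they all yield the same sign, the node
  takes that sign;
- *dead end*: an assigned node with no possible explanation left prunes
  the branch.

The search is complete and deterministic: witnesses are reproducible and
full enumeration emits solutions in lexicographic order of the
free-variable vector. Uncapped enumeration is refused above `2^20`
candidate labelings; callers must pass an explicit limit (reported back
with a truncation flag).

Cautious prediction uses two satisfiability queries per free variable
instead of enumeration: `v ↦ s` is emitted iff the instance with
`v = ¬s` is infeasible. Witnesses returned along the way are cached, and
any variable already seen with both signs across cached witnesses skips
its query. The test suite proves this equal to the literal intersection
of all enumerated solutions on an exhaustive sweep of small instances.

## Minimal inconsistent cores

A candidate member set `M` (non-input nodes) is judged on its induced
sub-problem: nodes `M ∪ pred(M)`, the edges into `M`, observations
restricted to that scope, and the explanation rule enforced only at the
members (non-members of the scope act as inputs). This "minimal
sub-graph" scoping keeps each core self-contained and auditable; the
alternative — global labelings with locally enforced rules — would let
constraints outside the reported sub-graph bind invisibly, and is
rejected for that reason.

Scope infeasibility is monotone under member-set inclusion, so
enumeration by increasing cardinality with superset pruning (no superset
of a found core is ever tested) returns exactly the minimal cores. The
default size cap is 8 members (`--max-mic-size`); MIC enumeration is the
most expensive operation in the package, as candidate counts grow
combinatorially.

## Minimal repairs

Repair atoms: `flip_obs(v)` (observed `v`), `make_input(v)` (non-input
`v`), `flip_edge(u,v)` (fixed-label edge), `add_edge(u,v,s)` (no
existing `u→v`, `u ≠ v`, `v` not an input; both signs offered per pair,
optionally restricted to a user-supplied candidate list to encode domain
hypotheses). Repairs are *cardinality*-minimal — "smallest number of
changes" — with every atom costing 1, also when several modes are
combined under one budget; all optima are enumerated, their intersection
reported as common repairs. The search is iterative deepening
`k = 0, 1, …` over slot-disjoint atom subsets, checking each candidate
by applying it and re-solving.

Without the `add` mode, every atom acts inside one weakly connected
component, and the minimum for the whole instance is the sum of
independent per-component minima; the instance is therefore decomposed
(via `networkx`), per-component optima are enumerated, and the global
repair sets are their cross-products. This is what makes enumerating
all minimal repairs on hundreds of random instances cheap. With `add`
enabled, edges may cross components and the search stays global.
Default size cap 8 (`--max-repair-size`); exceeding it yields an
explicit not-found report, not an error.

Predictions under repair intersect the achievable signs of each
variable across *all* consistent labelings of *all* minimally repaired
instances. The candidate variables are the free variables of the
original instance plus every observation/edge flipped by at least one
repair set: a flipped observation is fixed (to the flipped sign) in the
instances that flip it and to its original sign elsewhere, so an
observed node that every repair set flips surfaces with its corrected
sign — flagged via `PredictionTable.repaired_nodes` so downstream
exports can mark it as a suspect measurement rather than a plain
prediction.

## Synthetic data generator

`generate_consistent_instance` emulates a steady-state shift study:

| parameter | default | meaning |
|---|---|---|
| `n_nodes` | 30 | genes in the subnetwork |
| `edge_density` | 0.07 | per ordered pair (no self-loops); ≈ mean in-degree 2 at n = 30, the edge/node ratio of curated transcriptional networks |
| `input_fraction` | 0.1 | genes clamped as declared inputs |
| `obs_fraction` | 0.5 | genes with a measured variation |
| `unknown_edge_fraction` | 0.05 | regulations of unknown mode |
| `seed` | 0 | sole source of randomness |

Node signs are drawn uniformly; one incoming edge of every non-input
node is re-signed to explain its planted sign, making the planted
labelling a witness, hence consistency by construction. Observations
publish the planted signs of a random sample. `perturb_observations`
negates `m` observed signs to model corrupted measurements; the flips
are recorded so tests can assert that the inverse flip set (and hence
some repair of cardinality ≤ m) restores consistency. A flip does not
guarantee inconsistency — at mean degree ~2 roughly half of the
single-flip instances remain explainable, a rate the acceptance script
measures rather than assumes.

What the generator does **not** emulate: scale-free degree
distributions, autoregulation (no self-loops are generated, though
self-loops in input files are fully supported), expression magnitudes,
or correlated measurement noise. Passing tests therefore certify the
reasoning machinery, not robustness to the topology or noise structure
of any particular real dataset.

## Numerical / procedural choices

- Node identifiers are case-sensitive, whitespace-trimmed strings; at
  most one edge per ordered pair (identical duplicate input lines are
  deduplicated with a warning, conflicting ones are an error).
- Observation values of magnitude ≤ `--min-abs` (default 0, i.e. exact
  zeros) leave a node unobserved with a warning: the two-valued sign
  algebra has no null-variation value.
- All outputs are canonically ordered (lexicographic node ids; repair
  atoms by kind then ids; repair sets by their serialized form) so
  re-runs are byte-identical and parallel (`--jobs`) and serial runs
  produce identical trees. Concurrency granularity is one process per
  network; the solver itself is never parallelised.
- A bare identifier line in a network file declares an isolated node,
  so graphs with isolated nodes survive a write/read cycle.
- Exit codes: 0 success, 1 parse/validation error, 2 `check` found an
  inconsistency.

## Problem sizes used in the checks

The oracle-equivalence and MIC-validity sweeps cover every graph with
≤ 3 nodes and ≤ 4 edges, every `{+,-,?}` edge labelling and every
observation pattern (~350 000 instances; brute-force enumeration shares
work per graph across observation patterns). Randomised studies use
20–50-node instances at mean degree ~2 with 1–3 injected flips — 500
instances in the repair-recovery test, 200 in the acceptance script —
sizes at which exhaustive repair enumeration stays well below a minute
while exercising multi-component decomposition, multiple MICs and
non-trivial repair multiplicity.

## Known limitations

- Repair enumeration is exponential in the repair cardinality; the
  shared budget caps it, and `add` mode without a candidate list scales
  with `n²` atom candidates.
- MIC scoping judges each core on its induced sub-problem; cores whose
  infeasibility depends on constraints outside their scope are by
  design not reported (they are covered by larger cores).
- Cautious predictions are reported only for variables, never for
  observed, untouched nodes (their sign is not a deduction).
- The three-valued extension with a null-variation sign is out of
  scope.
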