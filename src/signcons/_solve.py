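"""Exact backtracking search for sign-consistent total labelings.

The decision problem — does a partial labeling extend to a total one in
which every non-input node is explained by some predecessor — is solved
by depth-first search over the free variables (unobserved nodes, then
UNKNOWN edges, both in lexicographic order) with unit-style propagation:

* if an explained node has exactly one undecided incoming contribution
  left and that contribution has a single unknown factor, the factor is
  forced;
* if all incoming contributions of an unassigned node are decided and
  they all produce the same sign, the node is forced to that sign;
* if an assigned node has no possible explanation left, the branch is
  pruned.

Branching tries PLUS before MINUS, so witnesses are deterministic and
full enumeration yields solutions in lexicographic order of the free
variable vector.
"""

from __future__ import annotations

from .model import (
    Edge,
    EdgeLabel,
    Instance,
    Sign,
    TotalLabeling,
    effective_inputs,
)

# internal encoding: signs are +1/-1, 0 means unassigned
_NODE = 0
_EDGE = 1


class CompiledInstance:
    """Index-based form of an :class:`Instance`, reusable across solves."""

    __slots__ = (
        "instance",
        "nodes",
        "node_index",
        "edges",
        "edge_index",
        "node_fixed",
        "edge_fixed",
        "non_input",
        "incoming",
        "node_watch",
        "edge_watch",
        "decisions",
        "free_node_count",
        "free_edge_count",
    )

    def __init__(self, instance: Instance) -> None:
        self.instance = instance
        graph = instance.graph
        self.nodes = sorted(graph.nodes)
        self.node_index = {name: i for i, name in enumerate(self.nodes)}
        self.edges = sorted(graph.edge_labels)
        self.edge_index = {e: j for j, e in enumerate(self.edges)}

        n, m = len(self.nodes), len(self.edges)
        obs = instance.observations.signs
        self.node_fixed = [
            obs[name].value if name in obs else 0 for name in self.nodes
        ]
        self.edge_fixed = [0] * m
        for j, e in enumerate(self.edges):
            s = graph.edge_labels[e].sign
            if s is not None:
                self.edge_fixed[j] = s.value

        exempt = effective_inputs(graph)
        self.non_input = [name not in exempt for name in self.nodes]

        self.incoming: list[list[tuple[int, int]]] = [[] for _ in range(n)]
        self.node_watch: list[list[int]] = [[] for _ in range(n)]
        self.edge_watch: list[int] = [-1] * m
        for j, (u, v) in enumerate(self.edges):
            ui, vi = self.node_index[u], self.node_index[v]
            if self.non_input[vi]:
                self.incoming[vi].append((ui, j))
                self.node_watch[ui].append(vi)
                self.edge_watch[j] = vi

        free_nodes = [i for i in range(n) if self.node_fixed[i] == 0]
        free_edges = [j for j in range(m) if self.edge_fixed[j] == 0]
        self.free_node_count = len(free_nodes)
        self.free_edge_count = len(free_edges)
        self.decisions = [(_NODE, i) for i in free_nodes] + [
            (_EDGE, j) for j in free_edges
        ]

    @property
    def free_variable_count(self) -> int:
        return self.free_node_count + self.free_edge_count

    def labeling(self, solution: tuple[tuple[int, ...], tuple[int, ...]]) -> TotalLabeling:
        ns, es = solution
        return TotalLabeling(
            node_signs={name: Sign(ns[i]) for i, name in enumerate(self.nodes)},
            edge_signs={e: Sign(es[j]) for j, e in enumerate(self.edges)},
        )


class _Search:
    __slots__ = ("c", "ns", "es", "trail", "solutions", "limit", "truncated")

    def __init__(self, c: CompiledInstance) -> None:
        self.c = c
        self.ns = list(c.node_fixed)
        self.es = list(c.edge_fixed)
        self.trail: list[tuple[int, int]] = []
        self.solutions: list[tuple[tuple[int, ...], tuple[int, ...]]] = []
        self.limit = 1
        self.truncated = False

    # -- assignment / propagation ------------------------------------

    def _assign(self, kind: int, idx: int, val: int, queue: list[int]) -> bool:
        if kind == _NODE:
            cur = self.ns[idx]
            if cur:
                return cur == val
            self.ns[idx] = val
            self.trail.append((_NODE, idx))
            queue.extend(self.c.node_watch[idx])
            if self.c.non_input[idx]:
                queue.append(idx)
        else:
            cur = self.es[idx]
            if cur:
                return cur == val
            self.es[idx] = val
            self.trail.append((_EDGE, idx))
            tgt = self.c.edge_watch[idx]
            if tgt >= 0:
                queue.append(tgt)
        return True

    def _propagate(self, queue: list[int]) -> bool:
        ns, es = self.ns, self.es
        incoming = self.c.incoming
        while queue:
            v = queue.pop()
            sv = ns[v]
            satisfied = False
            open_contribs: list[tuple[int, int, int, int]] = []
            seen = 0  # bit 0: a decided contribution yields +1; bit 1: -1
            for (u, e) in incoming[v]:
                su, se = ns[u], es[e]
                if su and se:
                    p = su * se
                    if sv:
                        if p == sv:
                            satisfied = True
                            break
                    else:
                        seen |= 1 if p == 1 else 2
                else:
                    open_contribs.append((u, e, su, se))
            if satisfied:
                continue
            if sv:
                if not open_contribs:
                    return False
                if len(open_contribs) == 1:
                    u, e, su, se = open_contribs[0]
                    if su and not se:
                        if not self._assign(_EDGE, e, sv * su, queue):
                            return False
                    elif se and not su:
                        if not self._assign(_NODE, u, sv * se, queue):
                            return False
                    # both factors free: either completion could work
            else:
                if not open_contribs:
                    # non-input => at least one incoming edge, so seen != 0
                    if seen == 1:
                        if not self._assign(_NODE, v, 1, queue):
                            return False
                    elif seen == 2:
                        if not self._assign(_NODE, v, -1, queue):
                            return False
        return True

    # -- search ------------------------------------------------------

    def run(self, assumptions: tuple[tuple[int, int, int], ...]) -> None:
        queue = [i for i, ni in enumerate(self.c.non_input) if ni]
        for kind, idx, val in assumptions:
            if not self._assign(kind, idx, val, queue):
                return
        if not self._propagate(queue):
            return
        self._dfs(0)

    def _dfs(self, start: int) -> bool:
        """Returns False when the solution limit is reached (stop search)."""
        decisions = self.c.decisions
        k = start
        while k < len(decisions):
            kind, idx = decisions[k]
            if (self.ns[idx] if kind == _NODE else self.es[idx]) == 0:
                break
            k += 1
        else:
            self.solutions.append((tuple(self.ns), tuple(self.es)))
            return len(self.solutions) < self.limit

        kind, idx = decisions[k]
        for val in (1, -1):
            mark = len(self.trail)
            queue: list[int] = []
            ok = self._assign(kind, idx, val, queue) and self._propagate(queue)
            if ok and not self._dfs(k + 1):
                return False
            while len(self.trail) > mark:
                tk, ti = self.trail.pop()
                if tk == _NODE:
                    self.ns[ti] = 0
                else:
                    self.es[ti] = 0
        return True


def search(
    compiled: CompiledInstance,
    assumptions: tuple[tuple[int, int, int], ...] = (),
    limit: int = 1,
) -> _Search:
    """Run the search; returns the search object with ``solutions`` filled.

    ``assumptions`` are extra ``(kind, index, value)`` fixings layered on
    top of the instance, used for cautious-reasoning queries.  ``limit``
    bounds the number of solutions collected; ``truncated`` is set when
    the limit cut off enumeration.
    """
    s = _Search(compiled)
    s.limit = limit
    s.run(assumptions)
    if len(s.solutions) >= limit:
        # limit reached; there may be more solutions
        s.truncated = True
    return s


def node_assumption(compiled: CompiledInstance, node: str, sign: Sign):
    return (_NODE, compiled.node_index[node], sign.value)


def edge_assumption(compiled: CompiledInstance, edge: Edge, sign: Sign):
    return (_EDGE, compiled.edge_index[edge], sign.value)
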