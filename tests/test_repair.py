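"""Repair atoms, minimal repair enumeration, and predictions under repair."""

from itertools import combinations

import pytest
from hypothesis import given, settings

from signcons.engine import solve
from signcons.model import Instance, ObservationSet, Sign
from signcons.repair import (
    RepairAtom,
    RepairError,
    RepairSet,
    apply_repair,
    candidate_atoms,
    common_repairs,
    minimal_repairs,
    predict_under_repair,
)
from signcons.synth import (
    GeneratorConfig,
    generate_consistent_instance,
    perturb_observations,
)

from helpers import inst, small_instances
from _oracles import oracle_consistent

P, M = Sign.PLUS, Sign.MINUS


def atom_lines(repair_set):
    return [a.to_line() for a in repair_set.sorted_atoms()]


class TestCandidateAtoms:
    def test_flip_obs_universe(self):
        i = inst(("A", "+", "B"), A="+", B="-")
        assert [a.to_line() for a in candidate_atoms(i, ("obs",))] == [
            "flip_obs\tA", "flip_obs\tB",
        ]

    def test_flip_edge_universe(self):
        i = inst(("A", "+", "B"), A="+", B="-")
        assert [a.to_line() for a in candidate_atoms(i, ("edge",))] == [
            "flip_edge\tA\tB",
        ]

    def test_unknown_edges_have_no_flip_candidate(self):
        i = inst(("A", "?", "B"))
        assert candidate_atoms(i, ("edge",)) == []

    def test_make_input_excludes_effective_inputs(self):
        i = inst(("A", "+", "B"), ("B", "+", "C"))
        assert [a.to_line() for a in candidate_atoms(i, ("input",))] == [
            "make_input\tB", "make_input\tC",
        ]

    def test_add_edge_universe_excludes_existing_selfloops_and_inputs(self):
        # nodes {A,B,C}, edge A->B, effective inputs {A,C}: only target B
        # is allowed, (A,B) exists, (B,B) is a self-loop -> C->B both signs
        i = inst(("A", "+", "B"), nodes=("C",))
        assert [a.to_line() for a in candidate_atoms(i, ("add",))] == [
            "add_edge\tC\tB\t+", "add_edge\tC\tB\t-",
        ]

    def test_add_candidates_restriction(self):
        i = inst(("A", "+", "B"), nodes=("C",))
        atoms = candidate_atoms(i, ("add",), add_candidates=[("C", "B")])
        assert len(atoms) == 2
        assert candidate_atoms(i, ("add",), add_candidates=[("A", "B")]) == []

    def test_empty_modes_rejected(self):
        with pytest.raises(ValueError):
            candidate_atoms(inst(("A", "+", "B")), ())


class TestApplyRepair:
    def test_flip_obs(self):
        i = inst(("A", "+", "B"), A="+", B="-")
        out = apply_repair(i, [RepairAtom("flip_obs", node="A")])
        assert out.observations.signs["A"] is M
        assert i.observations.signs["A"] is P  # original untouched

    def test_empty_repair_is_identity(self):
        i = inst(("A", "+", "B"), A="+", B="-")
        out = apply_repair(i, [])
        assert out.observations.signs == i.observations.signs
        assert out.graph.edge_labels == i.graph.edge_labels

    def test_flip_edge(self):
        i = inst(("A", "+", "B"))
        out = apply_repair(i, [RepairAtom("flip_edge", edge=("A", "B"))])
        assert out.graph.edge_labels[("A", "B")].value == "-"

    def test_make_input_and_add_edge(self):
        i = inst(("A", "+", "B"), nodes=("C",))
        out = apply_repair(i, [
            RepairAtom("make_input", node="B"),
            RepairAtom("add_edge", edge=("C", "B"), sign=M),
        ])
        assert "B" in out.graph.declared_inputs
        assert out.graph.edge_labels[("C", "B")].value == "-"

    @pytest.mark.parametrize("atom", [
        RepairAtom("flip_obs", node="B"),            # B unobserved
        RepairAtom("make_input", node="A"),          # A already an input
        RepairAtom("flip_edge", edge=("B", "A")),    # missing edge
        RepairAtom("add_edge", edge=("A", "B"), sign=P),  # edge exists
        RepairAtom("add_edge", edge=("B", "B"), sign=P),  # self-loop
    ])
    def test_invalid_atoms_rejected(self, atom):
        i = inst(("A", "+", "B"), A="+")
        with pytest.raises(RepairError):
            apply_repair(i, [atom])

    def test_slot_conflict_rejected(self):
        with pytest.raises(RepairError):
            RepairSet(frozenset({
                RepairAtom("add_edge", edge=("C", "B"), sign=P),
                RepairAtom("add_edge", edge=("C", "B"), sign=M),
            }))


class TestMinimalRepairs:
    def test_flip_obs_two_singletons(self):
        i = inst(("A", "+", "B"), A="+", B="-")
        report = minimal_repairs(i, ("obs",))
        assert report.minimal_cardinality == 1
        assert sorted(atom_lines(rs)[0] for rs in report.repair_sets) == [
            "flip_obs\tA", "flip_obs\tB",
        ]
        assert report.common == frozenset()

    def test_flip_edge_single_set_is_common(self):
        i = inst(("A", "+", "B"), A="+", B="-")
        report = minimal_repairs(i, ("edge",))
        assert report.minimal_cardinality == 1
        assert len(report.repair_sets) == 1
        assert report.common == {RepairAtom("flip_edge", edge=("A", "B"))}

    def test_two_failing_predecessors_any_flip_repairs(self):
        # U1=-, U2=- through + edges cannot explain X=+; flipping any of
        # the three observations restores consistency (one explaining
        # predecessor suffices), verified by exhaustive singleton sweep
        i = inst(("U1", "+", "X"), ("U2", "+", "X"), U1="-", U2="-", X="+")
        report = minimal_repairs(i, ("obs",))
        assert report.minimal_cardinality == 1
        assert sorted(atom_lines(rs)[0] for rs in report.repair_sets) == [
            "flip_obs\tU1", "flip_obs\tU2", "flip_obs\tX",
        ]
        assert report.common == frozenset()

    def test_constrained_chain_forces_target_flip(self):
        # V=- forces U1=-, which cannot explain X=+: flipping X is the
        # unique singleton repair (flipping V or U1 leaves the chain
        # unexplained), and the repaired instance forces X=-
        i = inst(("V", "+", "U1"), ("U1", "+", "X"), V="-", U1="-", X="+")
        report = minimal_repairs(i, ("obs",))
        assert report.minimal_cardinality == 1
        assert [atom_lines(rs) for rs in report.repair_sets] == [["flip_obs\tX"]]
        assert report.common == {RepairAtom("flip_obs", node="X")}
        assert report.predictions_under_repair.node_predictions["X"] is M

    def test_consistent_instance_yields_empty_repair(self):
        report = minimal_repairs(inst(("A", "+", "B"), A="+", B="+"), ("obs",))
        assert report.minimal_cardinality == 0
        assert len(report.repair_sets) == 1 and len(report.repair_sets[0]) == 0

    def test_not_found_within_budget(self):
        i = inst(("B", "+", "C"), ("C", "-", "B"))
        report = minimal_repairs(i, ("edge",), max_size=0)
        assert not report.found and report.repair_sets == []

    def test_add_mode_repairs_with_new_influence(self):
        # A=+ cannot explain B=-; a new edge from free node C can, with
        # either sign (C's sign is free)
        i = inst(("A", "+", "B"), nodes=("C",), A="+", B="-")
        report = minimal_repairs(i, ("add",))
        assert report.minimal_cardinality == 1
        assert sorted(atom_lines(rs)[0] for rs in report.repair_sets) == [
            "add_edge\tC\tB\t+", "add_edge\tC\tB\t-",
        ]

    def test_multi_mode_budget_is_shared(self):
        i = inst(("A", "+", "B"), A="+", B="-")
        report = minimal_repairs(i, ("obs", "edge"))
        assert report.minimal_cardinality == 1
        assert len(report.repair_sets) == 3  # flip A, flip B, flip edge

    def test_independent_components_combine(self):
        i = inst(
            ("A", "+", "B"), ("C", "+", "D"),
            A="+", B="-", C="+", D="-",
        )
        report = minimal_repairs(i, ("obs",))
        assert report.minimal_cardinality == 2
        assert len(report.repair_sets) == 4  # 2 choices per component


class TestCommonRepairs:
    @pytest.mark.parametrize("sets,expected", [
        ([{"a"}, {"a"}], {"a"}),
        ([{"a"}, {"b"}], set()),
        ([{"a", "b"}, {"a", "c"}], {"a"}),
    ])
    def test_intersection(self, sets, expected):
        import signcons.repair as rp

        atoms = {k: RepairAtom("flip_obs", node=k) for k in "abc"}
        report = rp.RepairReport(
            minimal_cardinality=len(sets[0]),
            repair_sets=[RepairSet(frozenset(atoms[k] for k in s)) for s in sets],
            common=frozenset(),
            predictions_under_repair=None,
        )
        assert common_repairs(report) == {atoms[k] for k in expected}


class TestPredictUnderRepair:
    def test_disagreeing_repairs_block_predictions(self):
        i = inst(("A", "+", "B"), A="+", B="-")
        report = minimal_repairs(i, ("obs",))
        table = report.predictions_under_repair
        assert table.scope == "under_repair"
        assert table.node_predictions == {}

    def test_observation_flipped_in_all_repairs_is_reported(self):
        # the observed-up target is flipped down by every minimal repair
        # set, so its down-regulation is a prediction under repair
        i = inst(("V", "+", "U1"), ("U1", "+", "X"), V="-", U1="-", X="+")
        table = minimal_repairs(i, ("obs",)).predictions_under_repair
        assert table.node_predictions["X"] is M
        assert "X" in table.repaired_nodes

    def test_requires_repair_sets(self):
        with pytest.raises(ValueError):
            predict_under_repair(inst(("A", "+", "B"), A="+"), [])


class TestRepairProperties:
    @given(small_instances(max_nodes=3, max_edges=4))
    @settings(max_examples=40)
    def test_matches_brute_force_subset_sweep(self, instance):
        report = minimal_repairs(
            instance, ("obs", "edge"), max_size=3, with_predictions=False
        )
        universe = candidate_atoms(instance, ("obs", "edge"))
        expected = None
        for k in range(0, 4):
            found = []
            for combo in combinations(universe, k):
                repaired = apply_repair(instance, combo)
                if oracle_consistent(repaired):
                    found.append(frozenset(combo))
            if found:
                expected = (k, sorted(found, key=lambda s: sorted(a.to_line() for a in s)))
                break
        if expected is None:
            assert not report.found
            return
        assert report.minimal_cardinality == expected[0]
        assert sorted(
            [rs.atoms for rs in report.repair_sets],
            key=lambda s: sorted(a.to_line() for a in s),
        ) == expected[1]

    @given(small_instances())
    @settings(max_examples=40)
    def test_every_repair_set_restores_consistency(self, instance):
        report = minimal_repairs(
            instance, ("obs", "input"), max_size=3, with_predictions=False
        )
        if not report.found:
            return
        for rs in report.repair_sets:
            assert solve(apply_repair(instance, rs)).consistent
        for rs in report.repair_sets:
            assert report.common <= rs.atoms

    def test_injected_flips_are_invertible(self):
        cfg = GeneratorConfig(n_nodes=20, edge_density=0.1, seed=5)
        instance, truth = generate_consistent_instance(cfg)
        perturbed, truth = perturb_observations(instance, truth, 3, seed=6)
        undo = [RepairAtom("flip_obs", node=v) for v in truth.injected_flips]
        assert solve(apply_repair(perturbed, undo)).consistent
        report = minimal_repairs(
            perturbed, ("obs",), with_predictions=False
        )
        assert report.found and report.minimal_cardinality <= 3
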