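import random
from math import comb

import pytest

from piecemeal import (
    EdgeRelation,
    Polarity,
    compute_class,
    degrees_of_freedom,
    dof_via_queries,
    enumerate_dags,
    parse_constraint,
    study_result_to_constraint,
)
from piecemeal.constraints import enumerate_study_designs
from piecemeal.dag import d_separated
from piecemeal.equivalence import EnumerationBackend, RelationAssertion
from piecemeal.simulation import Oracle


def satisfies(graph, c):
    separated = d_separated(graph, c.x, c.y, c.cond, c.intervened)
    return separated == (c.polarity is Polarity.INDEPENDENT)


def brute_force_class(variables, constraints):
    """Independent re-scoring pass: weigh every DAG directly.

    The knowledge base is a *set* of statements, so identical constraints
    arising from sign-variant studies count once.
    """
    constraints = set(constraints)
    graphs = enumerate_dags(variables)
    scores = [
        sum(c.weight for c in constraints if not satisfies(g, c)) for g in graphs
    ]
    best = min(scores)
    return {g for g, s in zip(graphs, scores) if s <= best + 1e-9}, best


class TestComputeClass:
    def test_empty_constraints_trivial_class(self):
        ec = compute_class(list("ABCD"), [])
        assert ec.size == 543
        assert ec.unsat_weight == 0.0

    def test_worked_three_variable_example(self, worked_class):
        """Marginal dependence everywhere plus X ⫫ Z | Y leaves the chain,
        the reversed chain, and the fork."""
        assert worked_class.size == 3
        assert worked_class.unsat_weight == 0.0
        edge_sets = {frozenset(g.edges) for g in worked_class.graphs}
        assert edge_sets == {
            frozenset({("X", "Y"), ("Y", "Z")}),  # chain
            frozenset({("Z", "Y"), ("Y", "X")}),  # reversed chain
            frozenset({("Y", "X"), ("Y", "Z")}),  # fork
        }

    def test_worked_example_matches_brute_force(self, worked_constraints):
        expected, weight = brute_force_class(["X", "Y", "Z"], worked_constraints)
        ec = compute_class(["X", "Y", "Z"], worked_constraints)
        assert ec.graphs == expected and weight == 0.0

    def test_weighted_conflict(self):
        """dep (w=2) vs indep (w=1) on a two-variable system: the two
        single-edge DAGs win with one unit of unsatisfied weight."""
        constraints = [
            parse_constraint("X dep Y ; w=2"),
            parse_constraint("X indep Y ; w=1"),
        ]
        ec = compute_class(["X", "Y"], constraints)
        assert ec.unsat_weight == pytest.approx(1.0)
        assert {frozenset(g.edges) for g in ec.graphs} == {
            frozenset({("X", "Y")}),
            frozenset({("Y", "X")}),
        }

    @pytest.mark.parametrize("seed", range(10))
    def test_weighted_argmin_matches_brute_force(self, seed):
        rng = random.Random(seed)
        variables = ["A", "B", "C"]
        designs = enumerate_study_designs(variables)
        constraints = [
            study_result_to_constraint(
                d,
                rng.choice([Polarity.DEPENDENT, Polarity.INDEPENDENT]),
                rng.choice([0.5, 1.0, 2.0]),
            )
            for d in rng.sample(designs, 8)
        ]
        expected, weight = brute_force_class(variables, constraints)
        ec = compute_class(variables, constraints)
        assert ec.graphs == expected
        assert ec.unsat_weight == pytest.approx(weight)
        assert ec.unsat_weight <= sum(c.weight for c in constraints)

    def test_conflict_free_monotonicity_and_duplicates(self):
        variables = ["A", "B", "C"]
        rng = random.Random(3)
        for _ in range(20):
            true = rng.choice(enumerate_dags(variables))
            oracle = Oracle(true)
            designs = rng.sample(enumerate_study_designs(variables), 6)
            constraints = [
                study_result_to_constraint(d, oracle.verdict(d)) for d in designs
            ]
            small = compute_class(variables, constraints[:3])
            big = compute_class(variables, constraints)
            assert small.unsat_weight == 0.0 == big.unsat_weight
            assert big.graphs <= small.graphs
            assert true in big
            duplicated = compute_class(variables, constraints + constraints[:2])
            assert duplicated.graphs == big.graphs


class TestDegreesOfFreedom:
    def test_worked_example_report(self, worked_class):
        report = degrees_of_freedom(worked_class)
        assert report.n[("X", "Y")] == 1
        assert report.n[("Y", "Z")] == 1
        assert report.n[("X", "Z")] == 0
        assert report.per_pair[("X", "Z")] == frozenset({EdgeRelation.NONE})
        assert report.total == 2
        assert report.percent_remaining == pytest.approx(100 * 2 / 6)

    def test_trivial_class_has_all_freedom(self):
        ec = compute_class(list("ABCD"), [])
        report = degrees_of_freedom(ec)
        assert report.total == 2 * comb(4, 2) == 12
        assert report.percent_remaining == 100.0

    def test_singleton_class_has_none(self):
        variables = ["A", "B", "C"]
        true = enumerate_dags(variables)[17]
        oracle = Oracle(true)
        constraints = [
            study_result_to_constraint(d, oracle.verdict(d))
            for d in enumerate_study_designs(variables)
        ]
        ec = compute_class(variables, constraints)
        if ec.size == 1:  # this true graph is fully identifiable
            assert degrees_of_freedom(ec).total == 0
        # regardless: total is zero iff the class is a singleton
        report = degrees_of_freedom(ec)
        assert (report.total == 0) == (ec.size == 1)


class CountingStubBackend:
    """Backend stub answering every query SATISFIABLE; counts calls."""

    def __init__(self):
        self.calls = 0

    def satisfiable(self, variables, constraints, assertion):
        assert isinstance(assertion, RelationAssertion)
        self.calls += 1
        return True


class TestQueryProtocol:
    def test_query_count_four_variables(self):
        report = dof_via_queries(list("ABCD"), [])
        assert report.n_queries == 3 * comb(4, 2) == 18

    def test_query_count_fourteen_variables_without_enumeration(self):
        backend = CountingStubBackend()
        variables = [f"v{i:02d}" for i in range(14)]
        report = dof_via_queries(variables, [], backend=backend)
        assert backend.calls == report.n_queries == 3 * comb(14, 2) == 273
        assert report.total == 2 * comb(14, 2)

    def test_worked_example_matches_enumeration_path(self, worked_constraints):
        by_query = dof_via_queries(["X", "Y", "Z"], worked_constraints)
        by_enum = degrees_of_freedom(
            compute_class(["X", "Y", "Z"], worked_constraints)
        )
        assert by_query.per_pair == by_enum.per_pair
        assert by_query.total == by_enum.total

    @pytest.mark.parametrize("seed", range(25))
    def test_agrees_with_enumeration_on_random_conflict_free_sets(self, seed):
        rng = random.Random(seed)
        variables = list("ABCD")
        true = rng.choice(enumerate_dags(variables))
        oracle = Oracle(true)
        designs = rng.sample(
            enumerate_study_designs(variables), rng.randint(1, 20)
        )
        constraints = [
            study_result_to_constraint(d, oracle.verdict(d)) for d in designs
        ]
        by_query = dof_via_queries(variables, constraints)
        by_enum = degrees_of_freedom(compute_class(variables, constraints))
        assert by_query.per_pair == by_enum.per_pair
        assert by_query.n == by_enum.n
        assert by_query.total == by_enum.total
        assert by_query.percent_remaining == by_enum.percent_remaining

    def test_backend_interface_accepts_predicates(self):
        backend = EnumerationBackend()
        assert backend.satisfiable(
            ["A", "B"], [], lambda g: ("A", "B") in g.edges
        )
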