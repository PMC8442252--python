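"""Equivalence classes of DAGs under weighted (in)dependence constraints.

The solver's contract is an argmin: among all candidate DAGs, keep every
graph minimizing the summed weight of unsatisfied constraints.  When the
constraints are mutually satisfiable the minimum is zero and the class is the
set of graphs satisfying them all (the usual constraint-based equivalence
class); conflicting evidence is resolved by the weighted minimum, with every
tie kept.

The default backend is exact enumeration: every constraint is evaluated once
per candidate graph and cached as a bitmask over the enumerated graph
universe, so repeated class computations (as in the simulation study) reduce
to integer bit arithmetic.  The backend interface is a single satisfiability
query — "is some optimal graph consistent with this assertion?" — so an
external solver could be plugged in for systems beyond enumeration capacity.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb
from typing import Callable, Iterable, Mapping, Protocol, Sequence

from .constraints import ConstraintLevelDesign, IndependenceConstraint, Polarity
from .dag import (
    DirectedAcyclicGraph,
    EdgeRelation,
    all_pairs,
    canonical_pair,
    d_separated,
    edge_relation,
    enumerate_dags,
    marginally_connected,
)
from .errors import CapacityError

#: Absolute tolerance for comparing summed constraint weights.
WEIGHT_TOL = 1e-9


class ExactEngine:
    """Memoized enumeration backend over all DAGs for a fixed variable set.

    Subsets of the graph universe are represented as Python integers used as
    bitmasks (bit ``i`` = graph ``i`` in enumeration order), so intersecting
    constraint verdicts and counting surviving graphs are single big-int
    operations.
    """

    def __init__(self, variables: Sequence[str], *, force: bool = False) -> None:
        self.variables = tuple(sorted(variables))
        self.graphs = enumerate_dags(self.variables, force=force)
        self.n_graphs = len(self.graphs)
        self.full_mask = (1 << self.n_graphs) - 1
        self.index = {g: i for i, g in enumerate(self.graphs)}
        self.pairs = all_pairs(self.variables)
        # relation masks: which graphs assign each relation to each pair
        self.relation_masks: dict[tuple[tuple[str, str], EdgeRelation], int] = {}
        for pair in self.pairs:
            masks = {rel: 0 for rel in EdgeRelation}
            for i, g in enumerate(self.graphs):
                masks[edge_relation(g, pair)] |= 1 << i
            for rel, m in masks.items():
                self.relation_masks[(pair, rel)] = m
        self._dsep_cache: dict[tuple, int] = {}

    # -- verdict masks -----------------------------------------------------

    def dsep_mask(
        self, x: str, y: str, cond: frozenset[str], intervened: frozenset[str]
    ) -> int:
        """Bitmask of graphs in which x ⫫ y | cond under the intervention."""
        key = (canonical_pair(x, y), cond, intervened)
        mask = self._dsep_cache.get(key)
        if mask is None:
            mask = 0
            if not cond:
                for i, g in enumerate(self.graphs):
                    if not marginally_connected(g.edges, x, y, intervened):
                        mask |= 1 << i
            else:
                for i, g in enumerate(self.graphs):
                    if d_separated(g, x, y, cond, intervened):
                        mask |= 1 << i
            self._dsep_cache[key] = mask
        return mask

    def constraint_mask(self, c: IndependenceConstraint) -> int:
        """Bitmask of graphs satisfying the constraint."""
        sep = self.dsep_mask(c.x, c.y, c.cond, c.intervened)
        return sep if c.polarity is Polarity.INDEPENDENT else self.full_mask & ~sep

    def dependence_mask(self, level: ConstraintLevelDesign) -> int:
        """Graphs in which the design's pair is dependent (the oracle's and
        the hypothesis engine's primitive)."""
        a, b = level.pair
        return self.full_mask & ~self.dsep_mask(a, b, frozenset(), level.intervened)

    # -- class computation -------------------------------------------------

    def class_mask(
        self, constraints: Iterable[IndependenceConstraint]
    ) -> tuple[int, float]:
        """(bitmask of optimal graphs, achieved unsatisfied weight)."""
        constraints = list(constraints)
        joint = self.full_mask
        for c in constraints:
            joint &= self.constraint_mask(c)
        if joint:
            return joint, 0.0
        # conflicting evidence: weighted argmin over the universe
        scores = [0.0] * self.n_graphs
        for c in constraints:
            unsat = self.full_mask & ~self.constraint_mask(c)
            idx = 0
            while unsat:
                low = unsat & -unsat
                scores[low.bit_length() - 1] += c.weight
                unsat ^= low
        best = min(scores)
        mask = 0
        for i, s in enumerate(scores):
            if s <= best + WEIGHT_TOL:
                mask |= 1 << i
        return mask, best

    def graphs_in(self, mask: int) -> list[DirectedAcyclicGraph]:
        out = []
        while mask:
            low = mask & -mask
            out.append(self.graphs[low.bit_length() - 1])
            mask ^= low
        return out

    def relations_present(
        self, mask: int, pair: tuple[str, str]
    ) -> frozenset[EdgeRelation]:
        return frozenset(
            rel for rel in EdgeRelation if mask & self.relation_masks[(pair, rel)]
        )


_ENGINES: dict[tuple[str, ...], ExactEngine] = {}


def get_engine(variables: Sequence[str], *, force: bool = False) -> ExactEngine:
    key = tuple(sorted(variables))
    engine = _ENGINES.get(key)
    if engine is None:
        engine = _ENGINES[key] = ExactEngine(key, force=force)
    return engine


# ---------------------------------------------------------------------------
# Equivalence classes
# ---------------------------------------------------------------------------


class EquivalenceClass:
    """The set of DAGs optimal under a constraint set.

    ``graphs`` is materialized lazily; ``size`` and per-pair relation queries
    go straight to the engine's bitmask.
    """

    def __init__(
        self,
        variables: Sequence[str],
        constraints: Iterable[IndependenceConstraint],
        *,
        engine: ExactEngine | None = None,
        mask: int | None = None,
        unsat_weight: float | None = None,
    ) -> None:
        self.variables = tuple(sorted(variables))
        self.constraints = frozenset(constraints)
        self._engine = engine or get_engine(self.variables)
        if mask is None:
            mask, unsat_weight = self._engine.class_mask(self.constraints)
        self.mask = mask
        self.unsat_weight = float(unsat_weight or 0.0)
        self._graphs: frozenset[DirectedAcyclicGraph] | None = None

    @property
    def size(self) -> int:
        return self.mask.bit_count()

    def __len__(self) -> int:
        return self.size

    @property
    def graphs(self) -> frozenset[DirectedAcyclicGraph]:
        if self._graphs is None:
            self._graphs = frozenset(self._engine.graphs_in(self.mask))
        return self._graphs

    def __contains__(self, g: DirectedAcyclicGraph) -> bool:
        i = self._engine.index.get(g)
        return i is not None and bool(self.mask >> i & 1)

    @property
    def engine(self) -> ExactEngine:
        return self._engine

    def relations_present(self, pair: tuple[str, str]) -> frozenset[EdgeRelation]:
        return self._engine.relations_present(self.mask, canonical_pair(*pair))

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"EquivalenceClass({len(self.variables)} variables, {self.size} graphs, "
            f"unsat_weight={self.unsat_weight:g})"
        )


def compute_class(
    variables: Sequence[str],
    constraints: Iterable[IndependenceConstraint],
    *,
    force: bool = False,
) -> EquivalenceClass:
    """Every DAG over ``variables`` achieving the minimum summed weight of
    unsatisfied constraints (zero when the constraints are conflict-free)."""
    return EquivalenceClass(
        variables, constraints, engine=get_engine(variables, force=force)
    )


# ---------------------------------------------------------------------------
# Degrees of freedom
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DoFReport:
    """Per-pair viable edge relations and the degrees-of-freedom tally.

    ``n[pair]`` counts the relations still viable beyond one (0..2); the
    total over all pairs, against the trivial maximum ``2*C(N,2)``, gives the
    percentage of underdetermination remaining.
    """

    per_pair: Mapping[tuple[str, str], frozenset[EdgeRelation]]
    n: Mapping[tuple[str, str], int]
    total: int
    percent_remaining: float
    n_queries: int | None = None

    def rows(self) -> list[tuple[tuple[str, str], frozenset[EdgeRelation], int]]:
        return [(p, self.per_pair[p], self.n[p]) for p in sorted(self.per_pair)]


def _report_from_relations(
    relations: Mapping[tuple[str, str], frozenset[EdgeRelation]],
    n_vars: int,
    n_queries: int | None = None,
) -> DoFReport:
    n = {pair: len(rels) - 1 for pair, rels in relations.items()}
    total = sum(n.values())
    return DoFReport(
        per_pair=dict(relations),
        n=n,
        total=total,
        percent_remaining=100.0 * total / (2 * comb(n_vars, 2)),
        n_queries=n_queries,
    )


def degrees_of_freedom(ec: EquivalenceClass) -> DoFReport:
    """DoF of a class by direct inspection of its graphs' edge relations."""
    if ec.size == 0:
        raise ValueError("cannot compute degrees of freedom of an empty class")
    relations = {pair: ec.relations_present(pair) for pair in ec.engine.pairs}
    return _report_from_relations(relations, len(ec.variables))


# ---------------------------------------------------------------------------
# Query-protocol path (satisfiability backend)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RelationAssertion:
    """Asserts that a pair takes one specific edge relation.

    RIGHT and LEFT assert the corresponding directed edge; NONE asserts that
    neither orientation is present.
    """

    pair: tuple[str, str]
    relation: EdgeRelation

    def __post_init__(self) -> None:
        object.__setattr__(self, "pair", canonical_pair(*self.pair))

    def holds_in(self, g: DirectedAcyclicGraph) -> bool:
        return edge_relation(g, self.pair) is self.relation


class SatisfiabilityBackend(Protocol):
    """One query: is some constraint-optimal graph consistent with the
    assertion?  For conflict-free constraints this is plain satisfiability of
    the union."""

    def satisfiable(
        self,
        variables: Sequence[str],
        constraints: Iterable[IndependenceConstraint],
        assertion,
    ) -> bool: ...


class EnumerationBackend:
    """Default backend: answers queries by exact enumeration (N ≤ capacity)."""

    def __init__(self, *, force: bool = False) -> None:
        self.force = force

    def satisfiable(self, variables, constraints, assertion) -> bool:
        engine = get_engine(variables, force=self.force)
        mask, _ = engine.class_mask(constraints)
        if isinstance(assertion, RelationAssertion):
            return bool(mask & engine.relation_masks[(assertion.pair, assertion.relation)])
        holds: Callable[[DirectedAcyclicGraph], bool] = (
            assertion.holds_in if hasattr(assertion, "holds_in") else assertion
        )
        return any(holds(g) for g in engine.graphs_in(mask))


def dof_via_queries(
    variables: Sequence[str],
    constraints: Iterable[IndependenceConstraint],
    backend: SatisfiabilityBackend | None = None,
) -> DoFReport:
    """Degrees of freedom via the query protocol: one satisfiability query
    per pair per candidate relation, ``3*C(N,2)`` queries total, without
    enumerating the class itself.  The issued query count is reported on the
    result."""
    variables = sorted(variables)
    if len(variables) < 2:
        raise ValueError("at least two variables are required")
    constraints = list(constraints)
    backend = backend or EnumerationBackend()
    relations: dict[tuple[str, str], frozenset[EdgeRelation]] = {}
    queries = 0
    for pair in all_pairs(variables):
        present = set()
        for rel in EdgeRelation:
            queries += 1
            if backend.satisfiable(variables, constraints, RelationAssertion(pair, rel)):
                present.add(rel)
        relations[pair] = frozenset(present)
    return _report_from_relations(relations, len(variables), n_queries=queries)
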