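"""Categorizing hypotheses by their utility for causal discovery.

Against a knowledge base of constraints, a hypothesis is consistent with
NONE, ALL, or SOME of the graphs in the equivalence class.  NONE and ALL
hypotheses are uninformative to test (their outcome is already entailed,
unless one distrusts the knowledge base); SOME hypotheses are the ones worth
pursuing — whatever the experiment shows, the class shrinks.

The category needs at most two satisfiability queries, not an enumeration
of the class: if kb ∪ h is unsatisfiable the category is NONE (one query);
otherwise kb ∪ ¬h decides between ALL (unsatisfiable — h is in the backbone)
and SOME.  A conflicting knowledge base is first reduced to its
weighted-optimal class, so "satisfiable" always means "holds in at least one
optimal graph".
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Sequence, Union

from .constraints import IndependenceConstraint, parse_constraint
from .dag import DirectedAcyclicGraph, canonical_pair, d_separated
from .equivalence import EnumerationBackend, SatisfiabilityBackend
from .errors import ParseError


class HypothesisCategory(Enum):
    NONE = "none"  # consistent with no graph in the class
    ALL = "all"  # consistent with every graph (in the backbone)
    SOME = "some"  # consistent with some but not all: worth testing


@dataclass(frozen=True)
class StructuralAssertion:
    """A structural hypothesis body about a single pair.

    ``orientation`` of ``(tail, head)`` with ``present=True`` asserts that
    directed edge; with ``present=False`` it asserts the edge's absence (the
    reverse orientation or no edge at all).  ``orientation=None`` speaks of
    the pair as a whole: ``present=False`` asserts no edge in either
    direction, ``present=True`` an edge in at least one.
    """

    pair: tuple[str, str]
    orientation: tuple[str, str] | None
    present: bool

    def __post_init__(self) -> None:
        object.__setattr__(self, "pair", canonical_pair(*self.pair))
        if self.orientation is not None and set(self.orientation) != set(self.pair):
            raise ValueError("orientation must involve exactly the pair's variables")

    def holds_in(self, g: DirectedAcyclicGraph) -> bool:
        if self.orientation is not None:
            return g.has_edge(*self.orientation) == self.present
        a, b = self.pair
        any_edge = g.has_edge(a, b) or g.has_edge(b, a)
        return any_edge == self.present


HypothesisBody = Union[IndependenceConstraint, StructuralAssertion]


@dataclass(frozen=True)
class Hypothesis:
    """A testable proposition: an (in)dependence statement or a structural
    assertion about an edge."""

    body: HypothesisBody

    @classmethod
    def dependence(cls, c: IndependenceConstraint) -> "Hypothesis":
        return cls(c)

    @classmethod
    def edge(cls, tail: str, head: str, present: bool = True) -> "Hypothesis":
        return cls(StructuralAssertion((tail, head), (tail, head), present))

    @classmethod
    def no_edge(cls, x: str, y: str) -> "Hypothesis":
        return cls(StructuralAssertion((x, y), None, False))

    def holds_in(self, g: DirectedAcyclicGraph) -> bool:
        if isinstance(self.body, IndependenceConstraint):
            c = self.body
            separated = d_separated(g, c.x, c.y, c.cond, c.intervened)
            return separated == (c.polarity.value == "indep")
        return self.body.holds_in(g)

    def __str__(self) -> str:
        if isinstance(self.body, IndependenceConstraint):
            return str(self.body)
        b = self.body
        if b.orientation is not None:
            arrow = f"edge {b.orientation[0]} -> {b.orientation[1]}"
            return arrow if b.present else f"no {arrow}"
        return (
            f"some edge between {b.pair[0]} and {b.pair[1]}"
            if b.present
            else f"no edge between {b.pair[0]} and {b.pair[1]}"
        )


def negate(h: Hypothesis) -> Hypothesis:
    """The hypothesis's negation; involutive (``negate(negate(h)) == h``)."""
    if isinstance(h.body, IndependenceConstraint):
        return Hypothesis(h.body.flipped())
    b = h.body
    return Hypothesis(StructuralAssertion(b.pair, b.orientation, not b.present))


@dataclass(frozen=True)
class CategorizationResult:
    category: HypothesisCategory
    queries: int


def categorize(
    variables: Sequence[str],
    kb: Iterable[IndependenceConstraint],
    h: Hypothesis,
    backend: SatisfiabilityBackend | None = None,
) -> CategorizationResult:
    """Category of ``h`` against the knowledge base, in one or two
    satisfiability queries (one exactly when the category is NONE)."""
    kb = list(kb)
    backend = backend or EnumerationBackend()
    if not backend.satisfiable(variables, kb, h):
        return CategorizationResult(HypothesisCategory.NONE, 1)
    if not backend.satisfiable(variables, kb, negate(h)):
        return CategorizationResult(HypothesisCategory.ALL, 2)
    return CategorizationResult(HypothesisCategory.SOME, 2)


def parse_hypothesis(text: str) -> Hypothesis:
    """Parse hypothesis text: the constraint notation (``X dep Y || X``), a
    directed edge (``edge X->Y`` / ``no edge X->Y``), or a pairwise absence
    (``no-edge X Y``)."""
    stripped = text.strip()
    low = stripped.lower()
    if low.startswith("no-edge"):
        names = stripped[7:].replace(",", " ").split()
        if len(names) != 2:
            raise ParseError(f"expected 'no-edge X Y', got {text!r}")
        return Hypothesis.no_edge(*names)
    negated = False
    if low.startswith("no "):
        stripped, negated = stripped[3:].strip(), True
        low = stripped.lower()
    if low.startswith("edge"):
        arrow = stripped[4:].strip()
        parts = [p.strip() for p in arrow.split("->")]
        if len(parts) != 2 or not all(parts):
            raise ParseError(f"expected 'edge TAIL->HEAD', got {text!r}")
        return Hypothesis.edge(parts[0], parts[1], present=not negated)
    if negated:
        raise ParseError(f"cannot parse hypothesis {text!r}")
    return Hypothesis(parse_constraint(stripped))
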