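"""Directed acyclic graphs over named variables.

A causal graph ``G = (V, D)`` is a set of variables plus directed edges, where
an edge ``x -> y`` states that ``x`` is a Markovian parent (direct cause) of
``y``.  This module provides the exact machinery the rest of the package is
built on: labeled-DAG counting and enumeration, d-separation in the
manipulated graph that results from an intervention (graph surgery), and the
per-pair edge relation (right / left / none) used to express degrees of
freedom.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from functools import lru_cache
from math import comb
from typing import Iterable, Iterator, Sequence

import networkx as nx

from .errors import CapacityError, ParseError

#: Exact enumeration is refused above this many variables unless forced;
#: the labeled-DAG count grows super-exponentially (over 3.7 million at six).
ENUMERATION_LIMIT = 6


class EdgeRelation(Enum):
    """The edge relation a pair of variables takes in a DAG.

    Reported with respect to the canonical (sorted) orientation of the pair
    ``(a, b)``: ``RIGHT`` is ``a -> b``, ``LEFT`` is ``a <- b``, ``NONE`` is
    no edge in either direction.  Cyclic graphs would add a fourth, mutual
    relation; only DAGs are modeled here.
    """

    RIGHT = "right"
    LEFT = "left"
    NONE = "none"


def canonical_pair(x: str, y: str) -> tuple[str, str]:
    """Return the unordered pair ``{x, y}`` in canonical (sorted) orientation."""
    if x == y:
        raise ValueError(f"a pair requires two distinct variables, got {x!r} twice")
    return (x, y) if x < y else (y, x)


@dataclass(frozen=True)
class DirectedAcyclicGraph:
    """An immutable labeled DAG.

    Parameters
    ----------
    variables:
        Ordered sequence of distinct variable names.
    edges:
        Directed edges ``(tail, head)``; ``tail`` is a parent of ``head``.
    """

    variables: tuple[str, ...]
    edges: frozenset[tuple[str, str]] = field(default_factory=frozenset)

    def __init__(
        self,
        variables: Sequence[str],
        edges: Iterable[tuple[str, str]] = (),
    ) -> None:
        object.__setattr__(self, "variables", tuple(variables))
        object.__setattr__(
            self, "edges", frozenset((str(t), str(h)) for t, h in edges)
        )
        self._validate()

    def _validate(self) -> None:
        if len(set(self.variables)) != len(self.variables):
            raise ValueError("variable names must be distinct")
        known = set(self.variables)
        for tail, head in self.edges:
            if tail == head:
                raise ValueError(f"self-loop on {tail!r} is not allowed")
            if tail not in known or head not in known:
                raise ValueError(f"edge ({tail!r}, {head!r}) uses unknown variables")
        if _has_cycle(self.variables, self.edges):
            raise ValueError("edge set contains a directed cycle")

    # -- structure ---------------------------------------------------------

    def parents(self, v: str) -> frozenset[str]:
        self._require(v)
        return frozenset(t for t, h in self.edges if h == v)

    def has_edge(self, tail: str, head: str) -> bool:
        return (tail, head) in self.edges

    def _require(self, *names: str) -> None:
        known = set(self.variables)
        for name in names:
            if name not in known:
                raise ValueError(f"unknown variable {name!r}")

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.variables)
        g.add_edges_from(self.edges)
        return g

    # -- serialization -----------------------------------------------------

    def to_edge_list_text(self) -> str:
        """Edge-list text: one ``TAIL -> HEAD`` line per edge, plus a
        ``NODE name`` line for each isolated variable."""
        touched = {v for e in self.edges for v in e}
        lines = [f"NODE {v}" for v in self.variables if v not in touched]
        lines += [f"{t} -> {h}" for t, h in sorted(self.edges)]
        return "\n".join(lines) + "\n"

    @classmethod
    def from_edge_list_text(cls, text: str) -> "DirectedAcyclicGraph":
        variables: list[str] = []
        edges: list[tuple[str, str]] = []

        def note(v: str) -> None:
            if v not in variables:
                variables.append(v)

        for lineno, raw in enumerate(text.splitlines(), start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if line.startswith("NODE "):
                note(line[5:].strip())
                continue
            parts = line.split("->")
            if len(parts) != 2:
                raise ParseError(f"line {lineno}: expected 'TAIL -> HEAD', got {raw!r}")
            tail, head = parts[0].strip(), parts[1].strip()
            if not tail or not head:
                raise ParseError(f"line {lineno}: empty endpoint in {raw!r}")
            note(tail)
            note(head)
            edges.append((tail, head))
        return cls(sorted(variables), edges)

    def to_json_dict(self) -> dict:
        return {
            "variables": list(self.variables),
            "edges": sorted([t, h] for t, h in self.edges),
        }

    @classmethod
    def from_json_dict(cls, doc: dict) -> "DirectedAcyclicGraph":
        return cls(doc["variables"], [tuple(e) for e in doc["edges"]])

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        es = ", ".join(f"{t}->{h}" for t, h in sorted(self.edges)) or "no edges"
        return f"DAG({', '.join(self.variables)}; {es})"


def _has_cycle(variables: Sequence[str], edges: Iterable[tuple[str, str]]) -> bool:
    g = nx.DiGraph()
    g.add_nodes_from(variables)
    g.add_edges_from(edges)
    return not nx.is_directed_acyclic_graph(g)


# ---------------------------------------------------------------------------
# Counting and enumeration
# ---------------------------------------------------------------------------


@lru_cache(maxsize=None)
def count_dags(n: int) -> int:
    """Number of labeled DAGs on ``n`` nodes, by the alternating-sign
    recurrence ``D(n) = sum_{k=1..n} (-1)^(k-1) C(n,k) 2^(k(n-k)) D(n-k)``
    with ``D(0) = 1``.

    Exact integer arithmetic throughout: the count overflows 64 bits well
    before the 14-variable systems the query protocol supports.
    """
    if not isinstance(n, int) or isinstance(n, bool):
        raise TypeError(f"n must be an integer, got {n!r}")
    if n < 0:
        raise ValueError(f"n must be non-negative, got {n}")
    if n == 0:
        return 1
    return sum(
        (-1) ** (k - 1) * comb(n, k) * 2 ** (k * (n - k)) * count_dags(n - k)
        for k in range(1, n + 1)
    )


def _ordered_pairs(variables: Sequence[str]) -> list[tuple[int, int]]:
    n = len(variables)
    return [(i, j) for i in range(n) for j in range(n) if i != j]


def enumerate_dags(
    variables: Sequence[str], *, force: bool = False
) -> list[DirectedAcyclicGraph]:
    """Every labeled DAG over ``variables``, exactly once, in lexicographic
    order of the adjacency encoding (row-major ordered pairs; absent < present,
    so the empty graph comes first).

    Refuses more than ``ENUMERATION_LIMIT`` variables unless ``force=True``.
    """
    variables = tuple(variables)
    n = len(variables)
    if n < 1:
        raise ValueError("at least one variable is required")
    if len(set(variables)) != n:
        raise ValueError("variable names must be distinct")
    if n > ENUMERATION_LIMIT and not force:
        raise CapacityError(
            f"enumeration of {n} variables exceeds the default limit of "
            f"{ENUMERATION_LIMIT} ({count_dags(n)} DAGs); pass force=True to override"
        )

    pairs = _ordered_pairs(variables)
    out: list[DirectedAcyclicGraph] = []
    edges: list[tuple[int, int]] = []
    adjacency: list[set[int]] = [set() for _ in range(n)]

    def reaches(src: int, dst: int) -> bool:
        stack = [src]
        seen = {src}
        while stack:
            node = stack.pop()
            if node == dst:
                return True
            for nxt in adjacency[node]:
                if nxt not in seen:
                    seen.add(nxt)
                    stack.append(nxt)
        return False

    def recurse(k: int) -> None:
        if k == len(pairs):
            out.append(
                DirectedAcyclicGraph(
                    variables, [(variables[i], variables[j]) for i, j in edges]
                )
            )
            return
        i, j = pairs[k]
        recurse(k + 1)  # pair absent first: lexicographic with 0 < 1
        if not reaches(j, i):  # adding i->j keeps the graph acyclic
            edges.append((i, j))
            adjacency[i].add(j)
            recurse(k + 1)
            adjacency[i].remove(j)
            edges.pop()

    recurse(0)
    return out


# ---------------------------------------------------------------------------
# d-separation under intervention
# ---------------------------------------------------------------------------


def manipulated_edges(
    g: DirectedAcyclicGraph, intervened: Iterable[str]
) -> frozenset[tuple[str, str]]:
    """Graph surgery: delete every edge whose head is intervened on.

    An intervention fixes its target experimentally, severing the target from
    its natural causes; intervened variables may still appear as tails.
    """
    cut = set(intervened)
    return frozenset(e for e in g.edges if e[1] not in cut)


def d_separated(
    g: DirectedAcyclicGraph,
    x: str,
    y: str,
    cond: Iterable[str] = (),
    intervened: Iterable[str] = (),
) -> bool:
    """True iff ``x`` and ``y`` are d-separated given ``cond`` in the
    manipulated graph obtained by intervening on ``intervened``.

    ``cond`` and ``intervened`` must be disjoint: a variable cannot be both
    statistically conditioned on and experimentally controlled in one
    statement.
    """
    cond = frozenset(cond)
    intervened = frozenset(intervened)
    g._require(x, y, *cond, *intervened)
    if x == y:
        raise ValueError("x and y must be distinct")
    if x in cond or y in cond:
        raise ValueError("x and y may not appear in the conditioning set")
    if cond & intervened:
        raise ValueError(
            f"variables {sorted(cond & intervened)} cannot be both conditioned "
            "on and intervened on"
        )
    surgered = nx.DiGraph()
    surgered.add_nodes_from(g.variables)
    surgered.add_edges_from(manipulated_edges(g, intervened))
    return nx.is_d_separator(surgered, {x}, {y}, set(cond))


def marginally_connected(
    edges: frozenset[tuple[str, str]],
    x: str,
    y: str,
    intervened: frozenset[str] = frozenset(),
) -> bool:
    """d-connection given the empty conditioning set, via the trek criterion.

    With nothing conditioned on, an active path can contain no collider, so
    ``x`` and ``y`` are d-connected iff they share a common ancestor
    (possibly ``x`` or ``y`` itself) in the manipulated graph.  This is the
    engine's fast path; the general case goes through :func:`d_separated`.
    """
    if intervened:
        edges = frozenset(e for e in edges if e[1] not in intervened)
    return bool(_ancestors(edges, x) & _ancestors(edges, y))


def _ancestors(edges: frozenset[tuple[str, str]], v: str) -> set[str]:
    anc = {v}
    frontier = [v]
    while frontier:
        node = frontier.pop()
        for tail, head in edges:
            if head == node and tail not in anc:
                anc.add(tail)
                frontier.append(tail)
    return anc


def edge_relation(
    g: DirectedAcyclicGraph, pair: tuple[str, str] | frozenset[str]
) -> EdgeRelation:
    """The relation ``g`` assigns to the unordered ``pair``, reported with
    respect to the pair's canonical (sorted) orientation."""
    a, b = sorted(pair)
    if a == b:
        raise ValueError("pair variables must be distinct")
    g._require(a, b)
    if (a, b) in g.edges:
        return EdgeRelation.RIGHT
    if (b, a) in g.edges:
        return EdgeRelation.LEFT
    return EdgeRelation.NONE


def relation_to_edges(
    pair: tuple[str, str], relation: EdgeRelation
) -> frozenset[tuple[str, str]]:
    """Directed edges a relation asserts for a canonical pair (empty for NONE)."""
    a, b = canonical_pair(*pair)
    if relation is EdgeRelation.RIGHT:
        return frozenset({(a, b)})
    if relation is EdgeRelation.LEFT:
        return frozenset({(b, a)})
    return frozenset()


def default_variables(n: int) -> tuple[str, ...]:
    """Canonical variable names A, B, C, ... used by simulations and the CLI."""
    if n < 1 or n > 26:
        raise ValueError("n must be between 1 and 26")
    return tuple(chr(ord("A") + i) for i in range(n))


def all_pairs(variables: Sequence[str]) -> list[tuple[str, str]]:
    """All C(N,2) canonical unordered pairs, deterministically ordered."""
    vs = sorted(variables)
    return [(vs[i], vs[j]) for i in range(len(vs)) for j in range(i + 1, len(vs))]
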