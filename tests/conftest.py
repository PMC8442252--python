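import itertools

import pytest

from piecemeal import compute_class, parse_constraint
from piecemeal.equivalence import get_engine


@pytest.fixture(scope="session")
def worked_constraints():
    """The three-variable textbook example: all pairs dependent marginally,
    X and Z independent given Y."""
    return [
        parse_constraint("X dep Y"),
        parse_constraint("Y dep Z"),
        parse_constraint("X dep Z"),
        parse_constraint("X indep Z | Y"),
    ]


@pytest.fixture(scope="session")
def worked_class(worked_constraints):
    return compute_class(["X", "Y", "Z"], worked_constraints)


@pytest.fixture(scope="session")
def engine4():
    return get_engine(("A", "B", "C", "D"))


def oracle_d_separated(graph, x, y, cond=(), intervened=()):
    """Independent d-separation oracle: enumerate every undirected simple
    path in the manipulated graph and apply the activation rules directly
    (collider active iff it or a descendant is conditioned on; non-collider
    active iff not conditioned on)."""
    cond = frozenset(cond)
    intervened = frozenset(intervened)
    edges = {e for e in graph.edges if e[1] not in intervened}

    def descendants(v):
        out = {v}
        frontier = [v]
        while frontier:
            node = frontier.pop()
            for tail, head in edges:
                if tail == node and head not in out:
                    out.add(head)
                    frontier.append(head)
        return out

    neighbors = {v: set() for v in graph.variables}
    for tail, head in edges:
        neighbors[tail].add(head)
        neighbors[head].add(tail)

    def paths(current, target, visited):
        if current == target:
            yield [current]
            return
        for nxt in neighbors[current]:
            if nxt not in visited:
                for rest in paths(nxt, target, visited | {nxt}):
                    yield [current] + rest

    for path in paths(x, y, {x}):
        active = True
        for i in range(1, len(path) - 1):
            prev, node, nxt = path[i - 1], path[i], path[i + 1]
            is_collider = (prev, node) in edges and (nxt, node) in edges
            if is_collider:
                if not (descendants(node) & cond):
                    active = False
                    break
            elif node in cond:
                active = False
                break
        if active:
            return False  # an active path d-connects x and y
    return True


def all_test_situations(variables, x, y):
    """Every legal (cond, intervened) combination for a pair: cond over the
    other variables, intervened over anything disjoint from cond."""
    others = [v for v in variables if v not in (x, y)]
    for r in range(len(others) + 1):
        for cond in itertools.combinations(others, r):
            rest = [v for v in variables if v not in cond]
            for s in range(len(rest) + 1):
                for intervened in itertools.combinations(rest, s):
                    yield frozenset(cond), frozenset(intervened)
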