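"""Experiment-selection policies over two-variable study designs.

Three policies choose the next study from the research-map design pool:

* ``random`` — uniform over unperformed designs (the evaluation baseline);
* ``dof`` — target the variable pair with the most degrees of freedom and
  run one of the experiments able to distinguish its remaining relations;
* ``expectation`` — enumerate the class, score every (pair, relation) by
  the expected number of graphs its confirmation would eliminate,
  ``e = (m/|E|) * (|E| - m)``, and test the top-scoring relation.

The suggested-experiment table encodes which designs can distinguish a
pair's viable relations.  The guiding exclusion: when the viable relations
are ``a -> b`` and "no edge", intervening on ``b`` is useless — the
intervention severs ``b`` from its causes, removing the very edge whose
presence is in question — so only the intervention on ``a`` and the passive
observation are suggested.
"""

from __future__ import annotations

import random
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence

from .constraints import (
    ConstraintLevelDesign,
    StudyDesign,
    enumerate_study_designs,
    to_constraint_level,
    variants_of,
)
from .dag import EdgeRelation, canonical_pair
from .equivalence import EquivalenceClass
from .errors import PoolExhausted

R, L, N = EdgeRelation.RIGHT, EdgeRelation.LEFT, EdgeRelation.NONE

# Suggested experiments per degree-of-freedom pattern, for the canonical pair
# (a, b): entries are "first" (intervene on a), "second" (intervene on b),
# "obs" (passive observation).  Multi-relation rows distinguish the pattern's
# remaining relations; single-relation rows (the expectation policy's input)
# name the experiments whose verdict bears on that one relation.
SUGGESTION_TABLE: dict[frozenset[EdgeRelation], frozenset[str]] = {
    frozenset({R, L, N}): frozenset({"first", "second"}),
    frozenset({R, L}): frozenset({"first", "second"}),
    frozenset({R, N}): frozenset({"first", "obs"}),
    frozenset({L, N}): frozenset({"second", "obs"}),
    frozenset({R}): frozenset({"first"}),
    frozenset({L}): frozenset({"second"}),
    frozenset({N}): frozenset({"first", "second"}),
}


def suggested_experiments(
    pair: tuple[str, str],
    pattern: Iterable[EdgeRelation] | EdgeRelation,
) -> frozenset[ConstraintLevelDesign]:
    """The constraint-level designs most informative for a pair, given the
    set of edge relations still viable for it (or a single relation)."""
    if isinstance(pattern, EdgeRelation):
        pattern = frozenset({pattern})
    else:
        pattern = frozenset(pattern)
    if not pattern:
        raise ValueError("pattern must contain at least one edge relation")
    a, b = canonical_pair(*pair)
    kinds = SUGGESTION_TABLE[pattern]
    out = set()
    if "obs" in kinds:
        out.add(ConstraintLevelDesign((a, b)))
    if "first" in kinds:
        out.add(ConstraintLevelDesign((a, b), frozenset({a})))
    if "second" in kinds:
        out.add(ConstraintLevelDesign((a, b), frozenset({b})))
    return frozenset(out)


@dataclass(frozen=True)
class ExpectationScore:
    """Expectation of a (pair, relation): the probability a class graph
    assigns the relation times the graphs eliminated if it is confirmed."""

    pair: tuple[str, str]
    relation: EdgeRelation
    m: int
    e: float


def expectation_scores(ec: EquivalenceClass) -> list[ExpectationScore]:
    """Scores ``e = (m/|E|)(|E|-m)`` for every pair and viable relation."""
    size = ec.size
    if size == 0:
        raise ValueError("cannot score an empty equivalence class")
    out = []
    for pair in ec.engine.pairs:
        for rel in EdgeRelation:
            m = (ec.mask & ec.engine.relation_masks[(pair, rel)]).bit_count()
            if m >= 1:
                out.append(
                    ExpectationScore(pair, rel, m, (m / size) * (size - m))
                )
    return out


class SelectionState:
    """Bookkeeping shared by the policies: the design pool, the multiset of
    performed designs P, the variables already selected, and the seeded RNG
    driving every random choice (so selection is reproducible)."""

    def __init__(self, variables: Sequence[str], seed: int = 0) -> None:
        self.variables = tuple(sorted(variables))
        self.pool: tuple[StudyDesign, ...] = tuple(enumerate_study_designs(variables))
        self.performed: Counter[StudyDesign] = Counter()
        self.variables_used: set[str] = set()
        self.rng = random.Random(seed)

    def record(self, design: StudyDesign) -> None:
        if design not in self.pool:
            raise ValueError(f"{design} is not in the design pool")
        self.performed[design] += 1
        self.variables_used.update({design.source, design.target})

    def unperformed(self) -> list[StudyDesign]:
        return [d for d in self.pool if self.performed[d] == 0]

    def level_count(self, level: ConstraintLevelDesign) -> int:
        """How often the constraint-level design is represented in P."""
        return sum(
            c for d, c in self.performed.items() if to_constraint_level(d) == level
        )

    def unperformed_variants(self, level: ConstraintLevelDesign) -> list[StudyDesign]:
        return [d for d in variants_of(level) if self.performed[d] == 0]


def _pick_variant(level: ConstraintLevelDesign, state: SelectionState) -> StudyDesign:
    # sign variants are informationally identical: draw uniformly
    options = sorted(state.unperformed_variants(level), key=StudyDesign.sort_key)
    return state.rng.choice(options)


def _fallback_random(state: SelectionState) -> StudyDesign:
    remaining = sorted(state.unperformed(), key=StudyDesign.sort_key)
    if not remaining:
        raise PoolExhausted("every study design in the pool has been performed")
    return state.rng.choice(remaining)


def select_random(state: SelectionState, pool: Sequence[StudyDesign] | None = None) -> StudyDesign:
    """Uniformly random unperformed design (the baseline policy)."""
    if pool is not None:
        remaining = sorted(
            (d for d in pool if state.performed[d] == 0), key=StudyDesign.sort_key
        )
        if not remaining:
            raise PoolExhausted("every study design in the pool has been performed")
        return state.rng.choice(remaining)
    return _fallback_random(state)


def select_dof(ec: EquivalenceClass, state: SelectionState) -> StudyDesign:
    """Degrees-of-freedom policy.

    Rank pairs by their DoF count ``n``; among the maximum-``n`` pairs take
    the suggested designs with at least one unperformed sign variant; prefer
    the constraint-level designs least represented in P, then those touching
    variables not previously selected; break remaining ties at random.  If
    every suggestion of every maximum-``n`` pair has been performed, fall
    back to a uniformly random unperformed design.
    """
    patterns = {pair: ec.relations_present(pair) for pair in ec.engine.pairs}
    n_max = max(len(rels) - 1 for rels in patterns.values())
    candidates: list[ConstraintLevelDesign] = []
    for pair, rels in patterns.items():
        if len(rels) - 1 == n_max:
            for level in suggested_experiments(pair, rels):
                if state.unperformed_variants(level):
                    candidates.append(level)
    if not candidates:
        return _fallback_random(state)
    counts = {level: state.level_count(level) for level in candidates}
    least = min(counts.values())
    candidates = [lv for lv in candidates if counts[lv] == least]
    novelty = {
        lv: sum(1 for v in lv.pair if v not in state.variables_used)
        for lv in candidates
    }
    freshest = max(novelty.values())
    candidates = sorted(
        (lv for lv in candidates if novelty[lv] == freshest),
        key=ConstraintLevelDesign.sort_key,
    )
    level = state.rng.choice(candidates)
    return _pick_variant(level, state)


def select_expectation(ec: EquivalenceClass, state: SelectionState) -> StudyDesign:
    """Expectation policy.

    Among (pair, relation) tuples whose suggested designs retain an
    unperformed variant, take the tuple with the highest expectation
    ``e = (m/|E|)(|E|-m)`` (random tie-break) and run one of the suggested
    experiments for that single relation; fall back to a random unperformed
    design when no suggestion remains.
    """
    scored = []
    for score in expectation_scores(ec):
        levels = [
            level
            for level in suggested_experiments(score.pair, score.relation)
            if state.unperformed_variants(level)
        ]
        if levels:
            scored.append((score, levels))
    if not scored:
        return _fallback_random(state)
    e_max = max(s.e for s, _ in scored)
    top = sorted(
        (
            (s, levels)
            for s, levels in scored
            if s.e >= e_max - 1e-12
        ),
        key=lambda item: (item[0].pair, item[0].relation.value),
    )
    score, levels = top[state.rng.randrange(len(top))]
    level = state.rng.choice(sorted(levels, key=ConstraintLevelDesign.sort_key))
    return _pick_variant(level, state)


POLICIES = {
    "random": "uniformly random unperformed design",
    "dof": "degrees-of-freedom policy",
    "expectation": "expectation policy",
}


def select(
    policy: str, ec: EquivalenceClass, state: SelectionState
) -> StudyDesign:
    """Dispatch on policy name ('random', 'dof', 'expectation')."""
    if policy == "random":
        return select_random(state)
    if policy == "dof":
        return select_dof(ec, state)
    if policy == "expectation":
        return select_expectation(ec, state)
    raise ValueError(f"unknown policy {policy!r}; expected one of {sorted(POLICIES)}")
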