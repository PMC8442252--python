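import math
from collections import Counter

import pytest

from piecemeal import (
    ConstraintLevelDesign,
    EdgeRelation,
    PoolExhausted,
    SelectionState,
    compute_class,
    expectation_scores,
    parse_constraint,
    select_dof,
    select_expectation,
    select_random,
    suggested_experiments,
)
from piecemeal.constraints import to_constraint_level

R, L, N = EdgeRelation.RIGHT, EdgeRelation.LEFT, EdgeRelation.NONE

OBS = ConstraintLevelDesign(("X", "Y"))
INT_X = ConstraintLevelDesign(("X", "Y"), frozenset({"X"}))
INT_Y = ConstraintLevelDesign(("X", "Y"), frozenset({"Y"}))


class TestSuggestionTable:
    @pytest.mark.parametrize(
        "pattern, expected",
        [
            ({R, N}, {INT_X, OBS}),  # never intervene on the effect side
            ({L, N}, {INT_Y, OBS}),  # mirror image
            ({R, L}, {INT_X, INT_Y}),
            ({R, L, N}, {INT_X, INT_Y}),
            ({R}, {INT_X}),
            ({L}, {INT_Y}),
            ({N}, {INT_X, INT_Y}),
        ],
    )
    def test_reconstructed_rows(self, pattern, expected):
        assert suggested_experiments(("X", "Y"), pattern) == frozenset(expected)

    def test_single_relation_accepted_bare(self):
        assert suggested_experiments(("X", "Y"), R) == frozenset({INT_X})

    def test_pair_order_is_canonicalized(self):
        assert suggested_experiments(("Y", "X"), {R, N}) == frozenset({INT_X, OBS})

    def test_empty_pattern_rejected(self):
        with pytest.raises(ValueError):
            suggested_experiments(("X", "Y"), set())

    def test_multi_relation_patterns_nonempty(self):
        for pattern in ({R, L}, {R, N}, {L, N}, {R, L, N}):
            assert suggested_experiments(("X", "Y"), pattern)


class TestExpectationScores:
    def test_worked_class_scores(self, worked_class):
        """|E| = 3: for the {X,Y} pair one graph says X->Y and two say X<-Y,
        so both orientations score e = 2/3."""
        scores = {
            (s.pair, s.relation): s for s in expectation_scores(worked_class)
        }
        assert scores[(("X", "Y"), R)].m == 1
        assert scores[(("X", "Y"), R)].e == pytest.approx(2 / 3)
        assert scores[(("X", "Y"), L)].m == 2
        assert scores[(("X", "Y"), L)].e == pytest.approx(2 / 3)
        # fixed relation: m = |E| gives zero reward
        assert scores[(("X", "Z"), N)].m == 3
        assert scores[(("X", "Z"), N)].e == 0.0

    def test_partition_property(self, worked_class):
        by_pair = Counter()
        for s in expectation_scores(worked_class):
            by_pair[s.pair] += s.m
        assert set(by_pair.values()) == {worked_class.size}

    def test_score_bound(self):
        ec = compute_class(list("ABC"), [])
        for s in expectation_scores(ec):
            assert 0 <= s.e <= ec.size / 4 + 1e-9
            assert (s.e == 0) == (s.m in (0, ec.size))


def fresh_state(variables=("X", "Y", "Z"), seed=0):
    return SelectionState(variables, seed)


class TestSelectRandom:
    def test_uniform_over_unperformed(self):
        state = fresh_state(seed=42)
        counts = Counter()
        for _ in range(6000):
            counts[select_random(state)] += 1
        assert set(counts) == set(state.pool)
        expected = 6000 / len(state.pool)
        for c in counts.values():  # ~5 sigma binomial band
            assert abs(c - expected) < 5 * math.sqrt(expected)

    def test_forced_last_design_and_exhaustion(self):
        state = fresh_state()
        designs = list(state.pool)
        for d in designs[:-1]:
            state.record(d)
        assert select_random(state) == designs[-1]
        state.record(designs[-1])
        with pytest.raises(PoolExhausted):
            select_random(state)

    def test_never_returns_performed(self):
        state = fresh_state(seed=1)
        for _ in range(len(state.pool)):
            design = select_random(state)
            assert state.performed[design] == 0
            state.record(design)


class TestSelectDof:
    def test_trivial_class_full_symmetry(self):
        """All pairs at n = 2: over many seeded draws every pair appears and
        every choice is one of that pattern's suggested interventions."""
        ec = compute_class(list("XYZ"), [])
        pairs_seen = set()
        for seed in range(300):
            design = select_dof(ec, fresh_state(seed=seed))
            level = to_constraint_level(design)
            assert not level.observational  # {R,L,N} suggests interventions only
            pairs_seen.add(level.pair)
        assert pairs_seen == {("X", "Y"), ("X", "Z"), ("Y", "Z")}

    def test_never_intervenes_on_effect_side(self):
        """Pattern {X->Y, none} on the only underdetermined pair: the policy
        must observe or intervene on X, never on Y."""
        constraints = [
            parse_constraint("X indep Z"),
            parse_constraint("Y indep Z"),
            parse_constraint("Y indep X || X"),  # rules out X -> Y
        ]
        ec = compute_class(list("XYZ"), constraints)
        patterns = {p: ec.relations_present(p) for p in ec.engine.pairs}
        assert patterns[("X", "Y")] == frozenset({L, N})
        assert all(len(patterns[p]) == 1 for p in (("X", "Z"), ("Y", "Z")))
        for seed in range(60):
            design = select_dof(ec, fresh_state(seed=seed))
            level = to_constraint_level(design)
            assert level.pair == ("X", "Y")
            assert level.intervened != frozenset({"X"})

    def test_fallback_when_suggestions_exhausted(self):
        """With every suggested design of every max-n pair performed, the
        policy falls back to a random unperformed design."""
        ec = compute_class(list("XYZ"), [])
        state = fresh_state(seed=5)
        # perform every interventional design (all suggestions of {R,L,N})
        interventional = [
            d for d in state.pool if to_constraint_level(d).intervened
        ]
        for d in interventional:
            state.record(d)
        design = select_dof(ec, state)
        assert to_constraint_level(design).observational

    def test_deterministic_under_seed(self):
        ec = compute_class(list("XYZ"), [])
        a = select_dof(ec, fresh_state(seed=9))
        b = select_dof(ec, fresh_state(seed=9))
        assert a == b

    def test_prefers_less_represented_levels(self):
        ec = compute_class(list("XYZ"), [])
        state = fresh_state(seed=2)
        first = select_dof(ec, state)
        state.record(first)
        second = select_dof(ec, state)
        assert to_constraint_level(second) != to_constraint_level(first)


class TestSelectExpectation:
    def test_zero_reward_relation_never_selected(self, worked_class):
        """In the worked class the {X,Z} no-edge relation is fixed (e = 0);
        positive-expectation orientation questions are always preferred."""
        for seed in range(60):
            design = select_expectation(worked_class, fresh_state(seed=seed))
            level = to_constraint_level(design)
            assert level.pair in {("X", "Y"), ("Y", "Z")}
            assert not level.observational  # orientations need interventions

    def test_deterministic_under_seed(self, worked_class):
        a = select_expectation(worked_class, fresh_state(seed=4))
        b = select_expectation(worked_class, fresh_state(seed=4))
        assert a == b

    def test_never_returns_performed_design(self, worked_class):
        state = fresh_state(seed=11)
        for _ in range(len(state.pool)):
            design = select_expectation(worked_class, state)
            assert state.performed[design] == 0
            state.record(design)
        with pytest.raises(PoolExhausted):
            select_expectation(worked_class, state)
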