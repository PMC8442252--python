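# Methods

This note records the scientific model the package implements, the choices
made where the design was genuinely open, and what the simulations do and do
not show.

## Model space and constraint semantics

The hypothesis space is the set of labeled DAGs over the system's variables.
Causal sufficiency is assumed (no latent confounders) and cycles are out of
scope: the fourth, mutual edge relation `X ⇄ Y` that a cyclic model space
would add is deliberately not represented.  The DAG count is computed by the
alternating-sign recurrence with exact integer arithmetic (`math.comb`,
Python big ints); the count exceeds 64 bits at 14 variables, which the
query-protocol path supports, so floating point is never used.

A constraint `X ⫫ Y | C ‖ J` (polarity: independent or dependent) is
evaluated against a DAG by graph surgery plus d-separation: delete every
edge whose head is in `J`, then test d-separation of `X` and `Y` given `C`.
Intervened variables may still appear as tails (an intervention sets its
target but does not stop the target influencing others).  Both bridge
principles are adopted: Markov (d-separation ⇒ independence) and
faithfulness (d-connection ⇒ dependence), so a dependent constraint is
violated exactly when the pair is d-separated.

General d-separation is delegated to `networkx.is_d_separator` on the
manipulated graph.  The engine's hot path — schema-generated constraints,
whose conditioning set is always empty because only two variables are
observed per study — uses a trek criterion instead: with nothing conditioned
on, no path through a collider is active, so d-connection is equivalent to
the two variables sharing a common ancestor (possibly one of the pair) in
the manipulated graph.  Both routes are checked in the test suite against an
independent oracle that enumerates all undirected simple paths and applies
the collider/non-collider activation rules directly, exhaustively over every
three-variable DAG and every legal conditioning/intervention combination.

## Equivalence classes and weights

The class is the argmin of summed unsatisfied-constraint weight over all
DAGs, with every tie kept.  The knowledge base is a *set* of constraints:
statements identical in pair, sets, polarity, and weight collapse, so sign
variants of one study design contribute once.  Weight sums are compared with
an absolute tolerance of 1e-9; weights default to 1.0 and may carry
research-map evidence scores (their Bayesian derivation is outside this
package's scope).

The default backend enumerates the universe once per variable set
(deterministic lexicographic order of the adjacency encoding) and caches
each constraint's verdict as a bitmask over it, so class computation is
big-integer intersection and class size is a popcount.  Enumeration refuses
more than six variables unless forced.  The satisfiability interface used by
the degrees-of-freedom query protocol and the hypothesis categorizer is a
single yes/no question — "does some optimal graph satisfy this assertion?" —
so an external ASP/SAT solver could replace enumeration for larger systems;
only the enumeration backend ships here.

Degrees of freedom count, per pair, the viable relations beyond one
(`n ≤ 2`), matching the worked three-variable example (total 2, ≈33% of
`2·C(3,2)`).  The query protocol issues exactly `3·C(N,2)` satisfiability
queries — one per pair per candidate relation — and is tested to agree with
the enumeration path on random conflict-free constraint sets.

## The study-design schema

For `N` variables the pool holds `4·N·(N−1)` designs: every ordered pair
with one of four methodological symbols (intervene-up, intervene-down,
observe-up, observe-down) — 48 designs at `N = 4`.  Direction of change and
correlation sign (excitation vs. inhibition) are metadata: a design's
information content is its *constraint-level design*, the pair plus which of
the pair (at most one) was intervened on, giving `3·C(N,2)` distinct
constraint-level designs (18 at `N = 4`), hit by 4 observational and 2 + 2
interventional sign variants per pair.  Conditioning sets are always empty
for schema-generated constraints, since a study observes only its two
variables; the constraint type retains `C` for user-supplied statements.

## The suggestion table

The table mapping a pair's viable-relation pattern to its informative
experiments is reconstructed from first principles rather than copied (only
its motivating rule survives in prose form): for pattern
{`a → b`, no edge}, intervening on `b` would sever `b` from its causes and
remove the very edge in question, so only the intervention on `a` and the
passive observation discriminate; the mirror pattern mirrors; patterns
containing both orientations map to the two interventions; single-relation
rows (used by the expectation policy) map RIGHT/LEFT to the intervention on
the tail side and the no-edge relation to both interventions — within a
larger system an observational dependence can arise from confounding paths,
so interventional verdicts are the cleaner discriminator of edge absence.
The table is centralized in `selection.SUGGESTION_TABLE` so an alternative
reconstruction can be swapped in one place.

## Selection policies

All three policies draw every random choice from one seeded RNG held in the
selection state, making each run a pure function of (class, state, seed).

*Random*: uniform over unperformed designs — the evaluation baseline.

*Degrees of freedom*: pairs are ranked by `n`; among maximum-`n` pairs the
suggested constraint-level designs with an unperformed sign variant are
preferred first by least representation in the performed multiset `P`
(counted at constraint-level granularity, since sign variants are
informationally identical), then by touching variables not previously
selected, with remaining ties uniform; the chosen level's concrete sign
variant is drawn uniformly from its unperformed variants.  If every
suggestion of every maximum-`n` pair is exhausted, a uniformly random
unperformed design is taken.

*Expectation*: for every pair and viable relation, `e = (m/|E|)(|E| − m)`
where `m` counts class graphs assigning that relation; the maximum-`e` tuple
with an unperformed suggested variant wins (uniform tie-break), with the
same fallback.

## Oracle simulation

One run fixes a true DAG, starts from the trivial class (543 graphs at
`N = 4`), and iterates until the pool is exhausted (48 steps); the oracle
returns a dependence verdict exactly when the design's pair is d-connected
in the manipulated true graph.  Verdicts and class updates go through the
memoized bitmask tables; the test suite replays recorded trajectories
through the public, memoization-free class computation to confirm identical
sizes.  The per-run seed is derived as
`crc32("policy:graph:rep") XOR (base_seed · 2654435761) mod 2³¹` and recorded
for replay.

The full study covers all 543 true graphs with five repetitions per policy
by default.  Summary first-passage numbers are read off the **averaged**
class-size curve: the first step at which the mean class size over all runs
drops below 50 or 10 graphs, or reaches the minimum mean value the
simulation achieves.  Per-run first crossings, averaged over runs, are
reported alongside; they are systematically earlier (converged runs keep
contributing their floor to the mean curve), and the averaged-curve reading
is the one matching the "minimum average number of graphs" framing this
summary is meant to mirror.  At four variables the maximum final class size
over all true graphs is 8, so every run crosses both thresholds; were a
threshold never crossed, the final step would be reported.

After every step, the hypothesis tracker categorizes the dependence-polarity
hypothesis of each untested design (48 − t of them; the independence
polarity would swap the NONE and ALL counts and leave SOME unchanged, by the
duality `category(h) = NONE ⇔ category(¬h) = ALL`).  The two-query
categorization protocol is tested against a direct scan of the class.

## Synthetic fixtures

The fixture generator samples a DAG by drawing edges only forward along a
random topological order (acyclic by construction; default edge probability
0.5, a neutral density given that the simulation study itself covers every
density exhaustively), samples study designs without replacement, and
answers them with the oracle — so generated research maps and constraint
files are conflict-free and their class always contains the generating
graph.  What the generator does *not* emulate: sampling noise, erroneous or
conflicting published results, latent confounding, and selection bias in
which studies get performed.  Passing tests on fixtures therefore validate
the synthesis and selection machinery, not robustness to unfaithful or noisy
real-world literatures (conflicts are exercised separately through weighted
constraints).

## Numerical and scale choices

Exact integer bit-arithmetic everywhere in the class engine; the only
floating point is constraint weights (1e-9 absolute tie tolerance) and
expectation scores (compared with a 1e-12 slack at the maximum).  The
default simulation scale — 543 true graphs × 5 repetitions × 3 policies —
runs in well under a minute on one CPU; the hypothesis-tracking study uses
one repetition per true graph, mirroring the averaging already provided by
the 543-graph sweep.

## Known limitations

- Enumeration capacity bounds exact computation at six variables; beyond
  that only the query protocol's bookkeeping (not its default backend) is
  usable, pending an external solver backend.
- The suggestion table is a reconstruction; small differences from other
  formulations of the same heuristic shift the degrees-of-freedom policy's
  trajectory by a step or two (the expectation and random policies are less
  sensitive).
- Hypotheses are limited to single-pair statements (structural or
  (in)dependence); compound hypotheses would need the solver-backend route.
- The research-map converter ingests the annotation schema but not the
  Bayesian evidence-score computation; scores are consumed as given.
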