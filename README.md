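# piecemeal

**Meta-analytic piecemeal causal discovery: equivalence classes, degrees of
freedom, and experiment selection for two-variable studies.**

In molecular and cellular biology, most published experiments relate just two
phenomena at a time — intervene on one variable and observe another, or
passively observe a pair — while the system under study has many more
variables.  Learning a system's causal structure from such *piecemeal*
evidence means combining many two-variable results analytically.  This
package is for scientists and methodologists who want to do that
synthesis formally: encode study results as constraints on causal structure,
see exactly which causal explanations remain viable, and decide which
experiment to run next.

## The model

A causal structure is a directed acyclic graph (DAG) `G = (V, D)`; an edge
`X → Y` says `X` is a direct cause of `Y`.  The number of labeled DAGs grows
super-exponentially, following

```
D(N) = Σ_{k=1..N} (−1)^{k−1} C(N,k) 2^{k(N−k)} D(N−k),   D(0) = 1,
```

so there are 1, 3, 25, 543 DAGs over 1–4 variables and about 1.1 × 10⁹ over
seven.

A study result is a constraint `X ⫫ Y | C ‖ J` (or its dependence
counterpart): the pair was found (in)dependent, conditioning on the set `C`,
in an experiment intervening on the set `J`.  Under the causal Markov and
faithfulness assumptions, a constraint holds in a DAG iff the corresponding
d-separation statement holds in the *manipulated* graph (every edge into an
intervened variable deleted).  Given weighted constraints `K`, the
**equivalence class** is the set of DAGs minimizing the summed weight of
unsatisfied constraints,

```
G* ∈ argmin_G Σ_{k ∈ K : G ⊭ k} w(k),
```

which reduces to the set of graphs satisfying all of `K` when the evidence is
conflict-free.

Underdetermination is quantified by **degrees of freedom**: for each pair of
variables, the edge relations (`X → Y`, `X ← Y`, no edge) realized somewhere
in the class, minus one; summed over pairs and compared to the trivial
maximum `2·C(N,2)`.  Two selection policies exploit this: the *degrees of
freedom* policy targets the most underdetermined pair with an experiment able
to distinguish its remaining relations, and the *expectation* policy scores
every (pair, relation) by `e = (m/|E|)·(|E| − m)` — the probability a class
graph assigns the relation times the number of graphs eliminated if it is
confirmed — and tests the top-scoring relation.  A hypothesis can further be
categorized, in at most two satisfiability queries, as consistent with
**none**, **all**, or **some** of the class — only the last kind is worth
testing, since its outcome is guaranteed to prune the class.

## Worked example

The textbook three-variable situation: all pairs correlate observationally,
but `X` and `Z` are independent given `Y`.

```bash
cat > worked.txt <<'EOF'
X dep Y
Y dep Z
X dep Z
X indep Z | Y
EOF
piecemeal solve --constraints worked.txt
```

```
variables: X, Y, Z
class size: 3
unsatisfied weight: 0
pair      relations              n
X-Y      left, right            1
X-Z      none                   0
Y-Z      left, right            1
total degrees of freedom: 2
percent remaining: 33.3%
```

Three graphs survive — the chain `X → Y → Z`, the reversed chain
`X ← Y ← Z`, and the fork `X ← Y → Z`.  They agree that `X` and `Z` share no
edge (`n = 0` for that pair) but disagree on both edge orientations: two
degrees of freedom, a third of the trivial maximum of six.  Asking what to do
next:

```bash
piecemeal suggest --constraints worked.txt --policy expectation --seed 1 --explain
```

```
pair      relation  m     e
X-Y      right     1     0.667
X-Y      left      2     0.667
Y-Z      right     2     0.667
Y-Z      left      1     0.667
X-Z      none      3     0.000
next study: X int_up -> Y
  (X↑ Y)
```

Every orientation question scores `e = 2/3` while the settled `X…Z` relation
scores zero; the policy suggests intervening on `X` and observing `Y` —
whichever way that study comes out, the class shrinks.  A hypothesis check
confirms that postulating a direct `X → Z` edge is pointless:

```bash
piecemeal categorize --kb worked.txt --hypothesis "edge X->Z"
```

```
hypothesis: edge X -> Z
category: none
queries used: 1
```

The same machinery is available as a library (`compute_class`,
`degrees_of_freedom`, `select_expectation`, `categorize`,
`run_full_study`, ...), and `piecemeal simulate` / `piecemeal fixture` run
oracle-driven studies and generate synthetic research maps.

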