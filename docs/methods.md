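# Methods

## Model

A dual hesitant fuzzy element (DHFE) d = (h, g) stores two finite sets of
grades in [0, 1]: the membership grades an assessor hesitates between, and
the nonmembership grades.  Elicited inputs satisfy max(h) + max(g) ≤ 1; a
singleton pair degenerates to an intuitionistic fuzzy value, h alone to a
hesitant fuzzy element.  A decision system consists of the diagnosis
universe U, the symptom universe V, one complete |U|×|V| DHFE relation per
expert, and a patient DHFS over V.

The rough approximation operators and the fusion, scoring and decision
steps are as stated in the README.  Everything is exact arithmetic on
small grade tuples; no iteration, no optimization, no randomness in the
pipeline itself.

## Lattice semantics: value filtering, not σ(k)

Two inequivalent conventions exist for joining/meeting hesitant sets, and
the choice matters more than it first appears.

* **Value filtering** (used here): the join of H₁…Hₙ keeps every grade of
  the pooled union that is ≥ maxᵢ min(Hᵢ); the meet keeps grades ≤
  minᵢ max(Hᵢ).  Result cardinalities vary.  The n-ary closed form equals
  every pairwise fold order (associativity and commutativity hold; the
  test suite checks all permutations on random operands).
* **σ(k) convention**: sort each operand descending, equalize lengths,
  operate position by position.

Only value filtering reproduces the packaged case study's published
approximation grids cell by cell, so the approximation operators use it
throughout.  The price is that several classically quoted lattice laws
fail:

* mutual distributivity of union and intersection (counterexample:
  memberships {0.1,0.9}, {0.2}, {0.8} give {0.1,0.8} nested vs
  {0.1,0.2,0.8} expanded);
* monotonicity of the approximations in the target set;
* the lower-∩ / upper-∪ homomorphisms;
* relation-monotonicity on cell-wise nested relations.

Each failure is frozen as a hand-checked counterexample test in
`tests/test_theorems.py`, and `tests/test_acceptance.py` keeps one test
asserting the σ(k)-only laws on 200 seeded instances — it fails by design
and documents the incompatibility.  The laws that *do* hold under value
filtering, verified on the same 200 seeded instances, are: double
negation, De Morgan, commutativity, associativity, lower/upper duality
under complement, the pessimistic ⊆ optimistic containments, the m = 1
reduction of both fusions to the single-granulation operator,
expert-permutation invariance, and the ⊕ monoid laws with identity
({0},{1}).

## Known discrepancies in the packaged case study

* The published optimistic lower membership at x2 is {0.6}; the defining
  formulas give {0.5,0.6} (the per-expert lowers {0.4,0.6}, {0.5,0.6},
  {0.5,0.6} — which the published pessimistic lower x2 cell {0.4,0.5,0.6}
  itself requires — join to {0.5,0.6}).  The package computes {0.5,0.6};
  the two optimistic x2 ⊕ components inherit the difference.  The final
  ranking is unaffected either way (both variants score x2 first; the
  decision test checks this robustness explicitly).
* Expert 2's table breaks the elicited bound at (x5,y3) and (x5,y4)
  (max(h)+max(g) = 1.1).  Loading therefore treats bound violations as
  warnings recorded on the instance (`ProblemInstance.bound_violations`);
  `load_instance(..., strict=True)` upgrades them to errors with cell
  coordinates.  Grade range and grid completeness are always hard errors.
  Derived elements (approximations, ⊕ results) are never re-validated
  against the bound — the pessimistic upper at x5 legitimately exceeds it.

## Numerical choices

* Canonical form: grades are rounded to 12 decimal places, deduplicated
  and sorted ascending at every element construction.  Equality of
  hesitant sets is tuple equality of canonical forms; this collapses
  float noise from ⊕ chains (two arithmetic paths to 0.88 differ by
  ~1e-16 in raw floats).
* Score ties: comparisons and argmax index sets use an absolute tolerance
  (default 1e-12, user-adjustable); all tied maximizers are kept, and
  rankings group tied labels rather than breaking ties by label order.
* Subset order: the σ(k) comparison sorts each part descending and
  extends the shorter part by repeating its last (smallest) value — the
  common length-equalization convention; it is used only for comparisons,
  never inside the approximation operators.
* DHFA is implemented as the standard dual of the geometric form:
  membership 1 − ∏(1 − γⱼ)^wⱼ, nonmembership ∏ηⱼ^wⱼ over the cartesian
  product of grade choices (DHFG mirrors it).  Weights default to equal
  1/n; arbitrary nonnegative weights summing to 1 (tolerance 1e-9) are
  accepted.
* The T₃ index set defaults to the score-maximizers of the four-way ⊕ of
  all four approximation sets.  An alternative reading — maximizers of the
  evenly weighted mean of the optimistic and pessimistic combined scores —
  is available as `t3_variant="mean-score"` for sensitivity analysis; on
  the packaged case study both give {x2}.

## Synthetic generator

`random_instance` emulates elicited knowledge bases: each cell draws
1..max_hesitancy membership grades uniformly on [0, 1] and nonmembership
grades uniformly on [0, 1 − max(h)], rounded to three decimals (clamped so
the elicited bound survives rounding), so every instance is valid by
construction.  Defaults used across the property suite are |U| = 4,
|V| = 5, m = 3, hesitancy ≤ 3 — the scale of the packaged case study —
and 200 seeded instances, which keeps the full suite within seconds while
exercising ragged cardinalities, duplicate collapses and boundary grades
(0 and 1 occur with probability ~1e-3 per grade only via rounding).  What
the generator does not emulate: correlated expert opinions, structured
missingness, or grades clustered on coarse scales as human elicitation
tends to produce; passing laws on synthetic instances therefore says
nothing about elicitation quality, only about the operators' algebra.

## Limitations

* The decision procedure is a ranking heuristic; no uncertainty measure or
  attribute reduction is provided.
* Score-based comparison is a total preorder that can rank an element with
  wide hesitancy above a narrow one at equal means; deviation-based
  refinements are out of scope.
* The σ(k)-only laws above genuinely fail under the implemented semantics;
  analyses that rely on approximation monotonicity should use the
  position-wise convention instead, which this package does not offer for
  the approximation operators.
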