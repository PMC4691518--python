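"""Element-level calculus of dual hesitant fuzzy elements.

A DHFE records the grades an assessor hesitates between, for membership
(h) and nonmembership (g) separately.  Union keeps pooled membership
grades clearing the larger lower bound (and dually for g); intersection is
the mirror image; the score mean(h) − mean(g) ranks elements; ⊕ is the
probabilistic-sum pooling law used to merge lower and upper evidence.
"""

from dhfrough import (
    DualHesitantElement,
    dhfe_complement,
    dhfe_intersection,
    dhfe_oplus,
    dhfe_score,
    dhfe_union,
)

d1 = DualHesitantElement.of((0.1, 0.4, 0.5), (0.2, 0.3))
d2 = DualHesitantElement.of((0.2, 0.3, 0.4), (0.4, 0.5))
print(f"d1 = {d1!r}")
print(f"d2 = {d2!r}")
print(f"complement of d1    : {dhfe_complement(d1)!r}   (h and g swap)")
print(f"union d1 ∨ d2       : {dhfe_union(d1, d2)!r}")
print(f"intersection d1 ∧ d2: {dhfe_intersection(d1, d2)!r}")
# union membership keeps grades ≥ max(0.1, 0.2) = 0.2 from {0.1,...,0.5}

a = DualHesitantElement.of((0.7, 0.8), (0.2, 0.3))
b = DualHesitantElement.of((0.4, 0.6), (0.2, 0.3))
print(f"score({a!r}) = {dhfe_score(a):.2f}")
print(f"score({b!r}) = {dhfe_score(b):.2f}  → the first ranks higher")

c = DualHesitantElement.of((0.3,), (0.6,))
print(f"{c!r} ⊕ {c!r} = {dhfe_oplus(c, c)!r}")
# membership 0.3 + 0.3 − 0.09 = 0.51; nonmembership 0.36: pooled support
# grows, pooled opposition shrinks
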