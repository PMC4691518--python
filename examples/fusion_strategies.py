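"""Optimistic vs pessimistic expert fusion, and the aggregation baseline.

Optimistic fusion joins the per-expert lower approximations (one expert's
support suffices — risk-seeking); pessimistic fusion meets them (all
experts must concur — risk-averse).  The pessimistic lower is always
contained in the optimistic lower, and the optimistic upper in the
pessimistic upper.  A simpler baseline collapses the experts first with an
averaging (DHFA) or geometric (DHFG) operator and approximates once.
"""

from dhfrough import (
    dhfs_subset,
    fuse_then_approximate,
    optimistic_approximations,
    pessimistic_approximations,
    worked_example,
)

instance = worked_example()
opt = optimistic_approximations(instance.relations, instance.patient)
pess = pessimistic_approximations(instance.relations, instance.patient)

print("containments between the two fusion strategies:")
print("  pessimistic lower ⊆ optimistic lower :", dhfs_subset(pess.lower, opt.lower))
print("  optimistic upper  ⊆ pessimistic upper:", dhfs_subset(opt.upper, pess.upper))

print("\nper-expert lower approximations at x2 (malaria), then their join:")
for i, single in enumerate(opt.per_expert, 1):
    print(f"  expert {i}: {single.lower['x2']!r}")
print(f"  optimistic (joined): {opt.lower['x2']!r}")
print(f"  pessimistic (met)  : {pess.lower['x2']!r}")

print("\naggregate-then-approximate baseline rankings:")
for operator in ("DHFG", "DHFA"):
    ranking = fuse_then_approximate(instance.relations, instance.patient, operator)
    print(f"  {operator}: " + " > ".join("~".join(g) for g in ranking))
# Both baselines reproduce the multigranulation ranking on this case, but
# they collapse the experts before approximating and so cannot distinguish
# risk attitudes.
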