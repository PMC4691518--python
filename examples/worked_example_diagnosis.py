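"""Diagnose the packaged fever case study.

Three experts relate five candidate diagnoses (viral fever, malaria,
typhoid, stomach problem, chest problem) to five symptoms; the patient
presents a dual hesitant grade pair per symptom.  The pipeline lifts the
patient profile to the diagnosis universe through each expert's relation,
fuses the experts optimistically and pessimistically, ⊕-combines lower and
upper evidence, scores, and applies the index-set decision rules.
"""

from dhfrough import diagnose, worked_example

instance = worked_example()
report = diagnose(instance.relations, instance.patient, metadata=instance.metadata)

print("optimistic lower/upper approximations over the diagnoses:")
for x in report.universe:
    print(f"  {x}: {report.optimistic.lower[x]!r}  /  {report.optimistic.upper[x]!r}")

print("\npessimistic lower/upper approximations:")
for x in report.universe:
    print(f"  {x}: {report.pessimistic.lower[x]!r}  /  {report.pessimistic.upper[x]!r}")

print("\nscores of the ⊕-combined sets (higher = better supported):")
for strategy in ("optimistic", "pessimistic", "combined"):
    row = ", ".join(f"{x}={s:.4f}" for x, s in report.scores[strategy].items())
    print(f"  {strategy:<12} {row}")

print()
print(report.summary())
# All three rankings agree (x2 > x4 > x1 > x3 > x5), every index set is
# {x2}, so rule 1 fires and the patient is diagnosed with malaria.
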