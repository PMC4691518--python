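"""The multigranulation diagnosis algorithm and its aggregation baseline.

Given m expert relations and a patient symptom profile, the procedure is:

1. compute the optimistic and pessimistic multigranulation lower/upper
   approximations of the patient set over the diagnosis universe;
2. ⊕-combine lower with upper within each strategy (the probabilistic-sum
   law pools necessity- and possibility-style evidence);
3. score every combined element (mean membership − mean nonmembership)
   and rank the diagnoses;
4. build the index sets T1 (optimistic score-maximizers), T2 (pessimistic
   score-maximizers) and T3 (maximizers of the four-way ⊕ of all four
   approximations), then decide:

   * rule 1:  T1 ∩ T2 ∩ T3 if nonempty;
   * rule 2a: else T1 ∩ T2 if nonempty;
   * rule 2b: else T3.

The "mean-score" T3 variant instead takes the maximizers of the average of
the optimistic and pessimistic combined scores — a literal reading of the
half-weighting of the two strategies; the four-way ⊕ construction is the
default.  For comparison, :func:`fuse_then_approximate` collapses the m
relations into one cell-wise with the DHFA or DHFG operator first and then
runs the single-granulation pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import reduce
from typing import Any, Mapping, Sequence

from .algebra import (
    SCORE_TOL,
    DualHesitantElement,
    DualHesitantSet,
    ValidationError,
    dhfa,
    dhfe_oplus,
    dhfe_score,
    dhfg,
)
from .rough import (
    ApproximationPair,
    DualHesitantRelation,
    optimistic_approximations,
    pessimistic_approximations,
    sg_approximations,
)

__all__ = [
    "IndexSets",
    "DiagnosisReport",
    "combine_oplus",
    "score_table",
    "rank_labels",
    "build_index_sets",
    "apply_decision_rules",
    "diagnose",
    "fuse_then_approximate",
]


@dataclass(frozen=True)
class IndexSets:
    """Score-maximizing diagnosis labels under the three fusion views."""

    t1: frozenset[str]
    t2: frozenset[str]
    t3: frozenset[str]


@dataclass(frozen=True)
class DiagnosisReport:
    """Every intermediate and the decision of one diagnosis run."""

    universe: tuple[str, ...]
    optimistic: ApproximationPair
    pessimistic: ApproximationPair
    combined_optimistic: DualHesitantSet
    combined_pessimistic: DualHesitantSet
    combined_all: DualHesitantSet
    scores: dict[str, dict[str, float]]
    rankings: dict[str, tuple[tuple[str, ...], ...]]
    index_sets: IndexSets
    rule_applied: str
    decision: frozenset[str]
    t3_variant: str = "oplus4"
    metadata: dict[str, Any] = field(default_factory=dict)

    def to_dict(self) -> dict[str, Any]:
        """A JSON-serializable view of the report."""

        def dhfs(ds: DualHesitantSet) -> dict[str, Any]:
            return {
                x: {"h": list(ds[x].h.values), "g": list(ds[x].g.values)}
                for x in ds.universe
            }

        return {
            "universe": list(self.universe),
            "approximations": {
                "optimistic_lower": dhfs(self.optimistic.lower),
                "optimistic_upper": dhfs(self.optimistic.upper),
                "pessimistic_lower": dhfs(self.pessimistic.lower),
                "pessimistic_upper": dhfs(self.pessimistic.upper),
            },
            "combined": {
                "optimistic": dhfs(self.combined_optimistic),
                "pessimistic": dhfs(self.combined_pessimistic),
                "all": dhfs(self.combined_all),
            },
            "scores": self.scores,
            "rankings": {
                k: [list(group) for group in v]
                for k, v in self.rankings.items()
            },
            "index_sets": {
                "T1": sorted(self.index_sets.t1),
                "T2": sorted(self.index_sets.t2),
                "T3": sorted(self.index_sets.t3),
            },
            "rule_applied": self.rule_applied,
            "decision": sorted(self.decision),
            "t3_variant": self.t3_variant,
            "metadata": self.metadata,
        }

    def summary(self) -> str:
        """Human-readable ranking table and decision."""
        lines = ["strategy      ranking (best first)"]
        for name, ranking in self.rankings.items():
            groups = " > ".join("~".join(g) for g in ranking)
            lines.append(f"{name:<13} {groups}")
        ix = self.index_sets
        lines.append(
            f"T1={sorted(ix.t1)} T2={sorted(ix.t2)} T3={sorted(ix.t3)}"
        )
        names = self.metadata.get("diagnosis_names", {})
        decided = ", ".join(
            f"{x} ({names[x]})" if x in names else x
            for x in sorted(self.decision)
        )
        lines.append(f"decision [{self.rule_applied}]: {decided}")
        return "\n".join(lines)


def combine_oplus(
    lower: DualHesitantSet, upper: DualHesitantSet
) -> DualHesitantSet:
    """Element-wise ⊕ of a lower and an upper approximation DHFS."""
    return lower._zip(upper, dhfe_oplus)


def score_table(ds: DualHesitantSet) -> dict[str, float]:
    """Score of every element, keyed by label."""
    return {x: dhfe_score(ds[x]) for x in ds.universe}


def rank_labels(
    scores: Mapping[str, float], tol: float = SCORE_TOL
) -> tuple[tuple[str, ...], ...]:
    """Labels grouped by score, best group first; ties (within ``tol``)
    share a group, ordered by the universe order of ``scores``."""
    ordered = sorted(scores, key=lambda x: -scores[x])
    groups: list[list[str]] = []
    for label in ordered:
        if groups and abs(scores[groups[-1][0]] - scores[label]) <= tol:
            groups[-1].append(label)
        else:
            groups.append([label])
    # within a tie group, keep the original key order for determinism
    order = {x: i for i, x in enumerate(scores)}
    return tuple(tuple(sorted(g, key=order.__getitem__)) for g in groups)


def _argmax(scores: Mapping[str, float], tol: float) -> frozenset[str]:
    best = max(scores.values())
    return frozenset(x for x, s in scores.items() if s >= best - tol)


def _four_way(
    opt: ApproximationPair, pess: ApproximationPair
) -> DualHesitantSet:
    return combine_oplus(
        combine_oplus(opt.lower, opt.upper),
        combine_oplus(pess.lower, pess.upper),
    )


def build_index_sets(
    relations: Sequence[DualHesitantRelation],
    patient: DualHesitantSet,
    t3_variant: str = "oplus4",
    tol: float = SCORE_TOL,
) -> IndexSets:
    """T1/T2/T3 for the given decision system (all maximizers kept)."""
    report = diagnose(relations, patient, t3_variant=t3_variant, tol=tol)
    return report.index_sets


def apply_decision_rules(ix: IndexSets) -> tuple[frozenset[str], str]:
    """First applicable rule: T1∩T2∩T3, then T1∩T2, then T3."""
    if not (ix.t1 and ix.t2 and ix.t3):
        raise ValidationError("index sets must be nonempty")
    all_three = ix.t1 & ix.t2 & ix.t3
    if all_three:
        return all_three, "rule1"
    both = ix.t1 & ix.t2
    if both:
        return both, "rule2a"
    return ix.t3, "rule2b"


def diagnose(
    relations: Sequence[DualHesitantRelation],
    patient: DualHesitantSet,
    t3_variant: str = "oplus4",
    tol: float = SCORE_TOL,
    metadata: Mapping[str, Any] | None = None,
) -> DiagnosisReport:
    """Run the full multigranulation diagnosis pipeline.

    Returns a report holding the four approximations, the ⊕-combined sets,
    scores and grouped rankings per strategy, the index sets, the applied
    rule and the (nonempty) decision set.
    """
    if t3_variant not in ("oplus4", "mean-score"):
        raise ValidationError(f"unknown t3_variant {t3_variant!r}")
    opt = optimistic_approximations(relations, patient)
    pess = pessimistic_approximations(relations, patient)
    comb_opt = combine_oplus(opt.lower, opt.upper)
    comb_pess = combine_oplus(pess.lower, pess.upper)
    comb_all = _four_way(opt, pess)

    scores = {
        "optimistic": score_table(comb_opt),
        "pessimistic": score_table(comb_pess),
        "combined": score_table(comb_all),
    }
    rankings = {k: rank_labels(v, tol) for k, v in scores.items()}

    t1 = _argmax(scores["optimistic"], tol)
    t2 = _argmax(scores["pessimistic"], tol)
    if t3_variant == "mean-score":
        mean_scores = {
            x: 0.5 * (scores["optimistic"][x] + scores["pessimistic"][x])
            for x in comb_all.universe
        }
        t3 = _argmax(mean_scores, tol)
    else:
        t3 = _argmax(scores["combined"], tol)
    index_sets = IndexSets(t1, t2, t3)
    decision, rule = apply_decision_rules(index_sets)
    return DiagnosisReport(
        universe=tuple(comb_all.universe),
        optimistic=opt,
        pessimistic=pess,
        combined_optimistic=comb_opt,
        combined_pessimistic=comb_pess,
        combined_all=comb_all,
        scores=scores,
        rankings=rankings,
        index_sets=index_sets,
        rule_applied=rule,
        decision=decision,
        t3_variant=t3_variant,
        metadata=dict(metadata or {}),
    )


def fuse_then_approximate(
    relations: Sequence[DualHesitantRelation],
    patient: DualHesitantSet,
    operator: str = "DHFG",
    tol: float = SCORE_TOL,
) -> tuple[tuple[str, ...], ...]:
    """Aggregate-then-approximate baseline.

    Collapses the m relations into one by applying the equal-weight DHFA or
    DHFG operator cell-wise, runs the single-granulation rough set,
    ⊕-combines lower with upper, scores, and returns the grouped ranking.
    """
    agg = {"DHFA": dhfa, "DHFG": dhfg}.get(operator.upper())
    if agg is None:
        raise ValidationError(f"unknown aggregation operator {operator!r}")
    if not relations:
        raise ValidationError("at least one relation is required")
    rows = relations[0].row_universe
    cols = relations[0].col_universe
    fused_cells: dict[tuple[str, str], DualHesitantElement] = {}
    for x in rows:
        for y in cols:
            fused_cells[(x, y)] = agg([r[x, y] for r in relations])
    fused = DualHesitantRelation(rows, cols, fused_cells, name=operator)
    pair = sg_approximations(fused, patient)
    combined = combine_oplus(pair.lower, pair.upper)
    return rank_labels(score_table(combined), tol)
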