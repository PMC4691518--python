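"""Dual hesitant fuzzy rough approximation operators over two universes.

A dual hesitant fuzzy *relation* links a decision universe U (diagnoses)
to a condition universe V (symptoms): one DHFE per (u, v) pair, typically
elicited from one expert.  Given a target DHFS ``A`` over V (a patient's
symptom profile), the rough set machinery produces *lower* and *upper*
approximation DHFSs over U — necessity- and possibility-style bounds on
how strongly each diagnosis is supported.

With m experts (m relations — m *granulations*) the per-expert
approximations are fused either optimistically ("seek common ground while
reserving differences": join the lowers, meet the uppers — risk-seeking)
or pessimistically ("seek common ground while eliminating differences":
meet the lowers, join the uppers — risk-averse).  With m = 1 both fusions
reduce to the single-granulation operator.

All joins/meets are the filtered-union semantics of :mod:`dhfrough.algebra`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from .algebra import (
    DualHesitantElement,
    DualHesitantSet,
    ValidationError,
    hfe_join,
    hfe_meet,
)

__all__ = [
    "DualHesitantRelation",
    "ApproximationPair",
    "sg_approximations",
    "optimistic_approximations",
    "pessimistic_approximations",
]


@dataclass(frozen=True)
class DualHesitantRelation:
    """A complete |U|×|V| grid of dual hesitant fuzzy elements.

    Every cell must have nonempty membership and nonmembership parts with
    grades in [0, 1].  Cells whose bounds break the elicited-input
    constraint ``max(h) + max(g) <= 1`` are accepted — published knowledge
    bases occasionally contain such cells — but are reported through
    :attr:`bound_violations` so callers may warn or reject.
    """

    row_universe: tuple[str, ...]
    col_universe: tuple[str, ...]
    cells: dict[tuple[str, str], DualHesitantElement]
    name: str = ""
    bound_violations: tuple[tuple[str, str], ...] = ()

    def __init__(
        self,
        row_universe: Sequence[str],
        col_universe: Sequence[str],
        cells: dict[tuple[str, str], DualHesitantElement],
        name: str = "",
    ) -> None:
        rows, cols = tuple(row_universe), tuple(col_universe)
        violations = []
        for x in rows:
            for y in cols:
                if (x, y) not in cells:
                    raise ValidationError(f"missing relation cell ({x}, {y})")
                cell = cells[(x, y)]
                if not cell.is_full_pair:
                    raise ValidationError(
                        f"cell ({x}, {y}): both h and g must be nonempty"
                    )
                if cell.violates_bound():
                    violations.append((x, y))
        extra = set(cells) - {(x, y) for x in rows for y in cols}
        if extra:
            raise ValidationError(f"cells outside the grid: {sorted(extra)}")
        object.__setattr__(self, "row_universe", rows)
        object.__setattr__(self, "col_universe", cols)
        object.__setattr__(self, "cells", dict(cells))
        object.__setattr__(self, "name", name)
        object.__setattr__(self, "bound_violations", tuple(violations))

    def __getitem__(self, key: tuple[str, str]) -> DualHesitantElement:
        return self.cells[key]


@dataclass(frozen=True)
class ApproximationPair:
    """Lower/upper approximation DHFSs over the decision universe U.

    ``strategy`` is one of ``"single"``, ``"optimistic"``, ``"pessimistic"``.
    For multigranulation strategies ``per_expert`` retains the
    single-granulation pair of each relation, in input order, for
    reporting and debugging.
    """

    lower: DualHesitantSet
    upper: DualHesitantSet
    strategy: str
    per_expert: tuple["ApproximationPair", ...] = field(default=())


def sg_approximations(
    relation: DualHesitantRelation, target: DualHesitantSet
) -> ApproximationPair:
    """Single-granulation rough approximations of ``target`` through
    ``relation``.

    For each diagnosis x, with cells (h_R, g_R) and target (h_A, g_A):

    * lower membership    = meet over y of join(g_R(x,y), h_A(y))
    * lower nonmembership = join over y of meet(h_R(x,y), g_A(y))
    * upper membership    = join over y of meet(h_R(x,y), h_A(y))
    * upper nonmembership = meet over y of join(g_R(x,y), g_A(y))
    """
    if tuple(target.universe) != relation.col_universe:
        raise ValidationError(
            "target universe does not match the relation's symptom universe"
        )
    lower: dict[str, DualHesitantElement] = {}
    upper: dict[str, DualHesitantElement] = {}
    for x in relation.row_universe:
        lo_h, lo_g, up_h, up_g = [], [], [], []
        for y in relation.col_universe:
            cell = relation[x, y]
            a = target[y]
            lo_h.append(hfe_join(cell.g, a.h))
            lo_g.append(hfe_meet(cell.h, a.g))
            up_h.append(hfe_meet(cell.h, a.h))
            up_g.append(hfe_join(cell.g, a.g))
        lower[x] = DualHesitantElement(hfe_meet(*lo_h), hfe_join(*lo_g))
        upper[x] = DualHesitantElement(hfe_join(*up_h), hfe_meet(*up_g))
    u = relation.row_universe
    return ApproximationPair(
        DualHesitantSet(u, lower), DualHesitantSet(u, upper), "single"
    )


def _per_expert(
    relations: Sequence[DualHesitantRelation], target: DualHesitantSet
) -> tuple[ApproximationPair, ...]:
    if not relations:
        raise ValidationError("at least one relation is required")
    first = relations[0]
    for r in relations[1:]:
        if (
            r.row_universe != first.row_universe
            or r.col_universe != first.col_universe
        ):
            raise ValidationError("relations disagree on the universes")
    return tuple(sg_approximations(r, target) for r in relations)


def _fuse(
    singles: Sequence[ApproximationPair],
    universe: tuple[str, ...],
    lower_h_op,
    strategy: str,
) -> ApproximationPair:
    # The three remaining component operators are forced by duality:
    # lower.g takes the opposite of lower.h, upper mirrors lower swapped.
    lower_g_op = hfe_meet if lower_h_op is hfe_join else hfe_join
    upper_h_op, upper_g_op = lower_g_op, lower_h_op
    lower = {
        x: DualHesitantElement(
            lower_h_op(*(s.lower[x].h for s in singles)),
            lower_g_op(*(s.lower[x].g for s in singles)),
        )
        for x in universe
    }
    upper = {
        x: DualHesitantElement(
            upper_h_op(*(s.upper[x].h for s in singles)),
            upper_g_op(*(s.upper[x].g for s in singles)),
        )
        for x in universe
    }
    return ApproximationPair(
        DualHesitantSet(universe, lower),
        DualHesitantSet(universe, upper),
        strategy,
        tuple(singles),
    )


def optimistic_approximations(
    relations: Sequence[DualHesitantRelation], target: DualHesitantSet
) -> ApproximationPair:
    """Optimistic multigranulation fusion: join the per-expert lower
    memberships (at least one expert's support suffices), meet the upper
    ones.  Reduces to :func:`sg_approximations` when m = 1."""
    singles = _per_expert(relations, target)
    return _fuse(singles, relations[0].row_universe, hfe_join, "optimistic")


def pessimistic_approximations(
    relations: Sequence[DualHesitantRelation], target: DualHesitantSet
) -> ApproximationPair:
    """Pessimistic multigranulation fusion: meet the per-expert lower
    memberships (every expert must concur), join the upper ones."""
    singles = _per_expert(relations, target)
    return _fuse(singles, relations[0].row_universe, hfe_meet, "pessimistic")
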