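"""Algebra of hesitant and dual hesitant fuzzy elements.

A *hesitant fuzzy element* (HFE) is a finite set of candidate membership
grades in [0, 1] for a single object — the device by which an assessor who
hesitates between, say, 0.7 and 0.8 records both.  A *dual hesitant fuzzy
element* (DHFE) pairs a membership HFE ``h`` with a nonmembership HFE ``g``,
subject (for elicited inputs) to ``max(h) + max(g) <= 1``.  A *dual hesitant
fuzzy set* (DHFS) assigns one DHFE to every label of a finite universe.

This module implements the element-level operational calculus the rest of
the package is built on:

* canonicalization (sorted, deduplicated grades),
* complement, and the *filtered* union/intersection — the union keeps every
  candidate grade from either operand that is at least the larger of the two
  lower bounds, the intersection every grade at most the smaller of the two
  upper bounds (with the dual rule on nonmembership grades),
* the score function ``mean(h) - mean(g)`` and the induced total preorder,
* the component-wise subset order on DHFSs,
* the probabilistic-sum law ``⊕`` and the averaging/geometric aggregation
  operators (DHFA / DHFG) over full cartesian products of value choices.

Everything is pure Python over small tuples; no numerics library is needed.
Grades are canonicalized by rounding to 12 decimal places so that values
reached along different floating-point paths compare equal.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Iterable, Iterator, Mapping, Sequence

__all__ = [
    "SCORE_TOL",
    "ValidationError",
    "HesitantSet",
    "DualHesitantElement",
    "DualHesitantSet",
    "normalize_hfe",
    "hfe_join",
    "hfe_meet",
    "dhfe_union",
    "dhfe_intersection",
    "dhfe_complement",
    "dhfe_score",
    "dhfe_compare",
    "dhfe_oplus",
    "dhfa",
    "dhfg",
    "dhfs_subset",
]

#: Absolute tolerance for score comparisons and weight-sum checks.
SCORE_TOL = 1e-12

_CANON_DECIMALS = 12


class ValidationError(ValueError):
    """An input violates a structural constraint of the model."""


def _canon_values(values: Iterable[float]) -> tuple[float, ...]:
    rounded = sorted(round(float(v), _CANON_DECIMALS) for v in values)
    out: list[float] = []
    for v in rounded:
        if not out or v != out[-1]:
            out.append(v)
    return tuple(out)


@dataclass(frozen=True)
class HesitantSet:
    """A finite set of grades in [0, 1], stored strictly increasing.

    The canonical form (sorted ascending, no duplicates) is established at
    construction; two hesitant sets are equal iff their canonical value
    tuples are equal.
    """

    values: tuple[float, ...]

    def __init__(self, values: Iterable[float]) -> None:
        canon = _canon_values(values)
        for v in canon:
            if not (0.0 <= v <= 1.0):
                raise ValidationError(f"grade {v!r} outside [0, 1]")
        object.__setattr__(self, "values", canon)

    def __iter__(self) -> Iterator[float]:
        return iter(self.values)

    def __len__(self) -> int:
        return len(self.values)

    def __bool__(self) -> bool:
        return bool(self.values)

    @property
    def lower(self) -> float:
        """Smallest grade (the h⁻ / g⁻ bound)."""
        if not self.values:
            raise ValidationError("empty hesitant set has no lower bound")
        return self.values[0]

    @property
    def upper(self) -> float:
        """Largest grade (the h⁺ / g⁺ bound)."""
        if not self.values:
            raise ValidationError("empty hesitant set has no upper bound")
        return self.values[-1]

    @property
    def mean(self) -> float:
        if not self.values:
            raise ValidationError("empty hesitant set has no mean")
        return math.fsum(self.values) / len(self.values)

    def descending(self, length: int | None = None) -> tuple[float, ...]:
        """Values sorted descending, optionally right-padded to ``length``
        by repeating the final (smallest) value.

        This is the σ(k) convention used by the subset order when the two
        hesitant sets being compared have different cardinalities.
        """
        desc = self.values[::-1]
        if length is None or length <= len(desc):
            return desc
        if not desc:
            raise ValidationError("cannot extend an empty hesitant set")
        return desc + (desc[-1],) * (length - len(desc))

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        inner = ",".join(format(v, "g") for v in self.values)
        return "{" + inner + "}"


EMPTY_HFE = HesitantSet(())


def normalize_hfe(raw: Iterable[float]) -> HesitantSet:
    """Canonicalize a raw collection of grades (sort, dedup, validate)."""
    return HesitantSet(raw)


def _require_nonempty(sets: Sequence[HesitantSet], op: str) -> None:
    if not sets:
        raise ValidationError(f"{op} needs at least one operand")
    for hs in sets:
        if not hs:
            raise ValidationError(f"{op} is undefined on empty hesitant sets")


def hfe_join(*sets: HesitantSet) -> HesitantSet:
    """Filtered union of hesitant sets.

    Keeps every grade from the pooled operands that is at least the largest
    of the operand minima; equals any pairwise left-fold of the binary union
    in any order.  The surviving set is never empty (the defining bound
    itself always survives).
    """
    _require_nonempty(sets, "join")
    bound = max(hs.lower for hs in sets)
    pooled = itertools.chain.from_iterable(hs.values for hs in sets)
    return HesitantSet(v for v in pooled if v >= bound)


def hfe_meet(*sets: HesitantSet) -> HesitantSet:
    """Filtered intersection: pooled grades at most the smallest maximum."""
    _require_nonempty(sets, "meet")
    bound = min(hs.upper for hs in sets)
    pooled = itertools.chain.from_iterable(hs.values for hs in sets)
    return HesitantSet(v for v in pooled if v <= bound)


@dataclass(frozen=True)
class DualHesitantElement:
    """A pair (membership hesitancy, nonmembership hesitancy).

    Elicited inputs additionally satisfy ``max(h) + max(g) <= 1``
    (checked by :meth:`validate_input`); elements derived by approximation
    or ⊕ are not required to, and :meth:`violates_bound` flags — without
    rejecting — those that do not.
    """

    h: HesitantSet
    g: HesitantSet

    @classmethod
    def of(
        cls, h: Iterable[float], g: Iterable[float]
    ) -> "DualHesitantElement":
        return cls(HesitantSet(h), HesitantSet(g))

    @property
    def is_full_pair(self) -> bool:
        return bool(self.h) and bool(self.g)

    def validate_input(self, where: str = "element") -> "DualHesitantElement":
        """Enforce the elicited-input constraints; returns self."""
        if not self.h or not self.g:
            raise ValidationError(f"{where}: both h and g must be nonempty")
        if self.h.upper + self.g.upper > 1.0 + SCORE_TOL:
            raise ValidationError(
                f"{where}: max membership {self.h.upper} + max nonmembership "
                f"{self.g.upper} exceeds 1"
            )
        return self

    def violates_bound(self) -> bool:
        """True if ``max(h) + max(g) > 1`` (possible for derived elements)."""
        return self.h.upper + self.g.upper > 1.0 + SCORE_TOL

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"⟨{self.h!r},{self.g!r}⟩"


#: Identity of the ⊕ law and the element of the empty DHFS.
EMPTY_ELEMENT = DualHesitantElement.of((0.0,), (1.0,))
#: The element of the full DHFS.
FULL_ELEMENT = DualHesitantElement.of((1.0,), (0.0,))


def _require_full(elements: Sequence[DualHesitantElement], op: str) -> None:
    for d in elements:
        if not d.is_full_pair:
            raise ValidationError(
                f"{op} requires elements with nonempty h and g parts"
            )


def dhfe_union(
    d1: DualHesitantElement, d2: DualHesitantElement
) -> DualHesitantElement:
    """Element union: filtered join on memberships, meet on nonmemberships."""
    _require_full((d1, d2), "union")
    return DualHesitantElement(hfe_join(d1.h, d2.h), hfe_meet(d1.g, d2.g))


def dhfe_intersection(
    d1: DualHesitantElement, d2: DualHesitantElement
) -> DualHesitantElement:
    """Element intersection: meet on memberships, join on nonmemberships."""
    _require_full((d1, d2), "intersection")
    return DualHesitantElement(hfe_meet(d1.h, d2.h), hfe_join(d1.g, d2.g))


def dhfe_complement(d: DualHesitantElement) -> DualHesitantElement:
    """Complement of a DHFE.

    For a full pair the two hesitancy sets swap roles.  The degenerate
    single-sided branches map each grade v to 1 − v on the populated side.
    """
    if d.h and d.g:
        return DualHesitantElement(d.g, d.h)
    if d.h:
        return DualHesitantElement(HesitantSet(1.0 - v for v in d.h), EMPTY_HFE)
    if d.g:
        return DualHesitantElement(EMPTY_HFE, HesitantSet(1.0 - v for v in d.g))
    raise ValidationError("complement undefined when both parts are empty")


def dhfe_score(d: DualHesitantElement) -> float:
    """Score ``mean(h) − mean(g)``, in [−1, 1]."""
    _require_full((d,), "score")
    return d.h.mean - d.g.mean


def dhfe_compare(
    d1: DualHesitantElement,
    d2: DualHesitantElement,
    tol: float = SCORE_TOL,
) -> str:
    """Compare two elements by score.

    Returns ``"succeeds"`` if d1 ranks above d2, ``"precedes"`` if below,
    ``"equivalent"`` when the scores agree within ``tol``.
    """
    s1, s2 = dhfe_score(d1), dhfe_score(d2)
    if abs(s1 - s2) <= tol:
        return "equivalent"
    return "succeeds" if s1 > s2 else "precedes"


def dhfe_oplus(
    d1: DualHesitantElement, d2: DualHesitantElement
) -> DualHesitantElement:
    """Probabilistic-sum combination ⊕ of two full DHFEs.

    Memberships are all pairwise γ1 + γ2 − γ1·γ2, nonmemberships all
    pairwise η1·η2, each canonicalized.  Commutative and associative with
    identity ({0}, {1}).
    """
    _require_full((d1, d2), "⊕")
    h = (a + b - a * b for a, b in itertools.product(d1.h, d2.h))
    g = (a * b for a, b in itertools.product(d1.g, d2.g))
    return DualHesitantElement(HesitantSet(h), HesitantSet(g))


def _check_weights(
    elements: Sequence[DualHesitantElement], weights: Sequence[float] | None
) -> tuple[float, ...]:
    if not elements:
        raise ValidationError("aggregation needs at least one element")
    _require_full(elements, "aggregation")
    n = len(elements)
    if weights is None:
        return (1.0 / n,) * n
    w = tuple(float(x) for x in weights)
    if len(w) != n:
        raise ValidationError(
            f"{len(w)} weights supplied for {n} elements"
        )
    if any(x < 0 for x in w):
        raise ValidationError("weights must be nonnegative")
    if abs(math.fsum(w) - 1.0) > 1e-9:
        raise ValidationError(f"weights sum to {math.fsum(w)}, expected 1")
    return w


def dhfa(
    elements: Sequence[DualHesitantElement],
    weights: Sequence[float] | None = None,
) -> DualHesitantElement:
    """Dual hesitant fuzzy averaging (DHFA) aggregation.

    Over every choice of one grade per element: membership
    ``1 − ∏ (1 − γj)^wj`` and nonmembership ``∏ ηj^wj``.  Weights default
    to equal 1/n.
    """
    w = _check_weights(elements, weights)
    h = (
        1.0 - math.prod((1.0 - γ) ** wj for γ, wj in zip(choice, w))
        for choice in itertools.product(*(d.h for d in elements))
    )
    g = (
        math.prod(η**wj for η, wj in zip(choice, w))
        for choice in itertools.product(*(d.g for d in elements))
    )
    return DualHesitantElement(HesitantSet(h), HesitantSet(g))


def dhfg(
    elements: Sequence[DualHesitantElement],
    weights: Sequence[float] | None = None,
) -> DualHesitantElement:
    """Dual hesitant fuzzy geometric (DHFG) aggregation.

    Over every choice of one grade per element: membership ``∏ γj^wj`` and
    nonmembership ``1 − ∏ (1 − ηj)^wj``.
    """
    w = _check_weights(elements, weights)
    h = (
        math.prod(γ**wj for γ, wj in zip(choice, w))
        for choice in itertools.product(*(d.h for d in elements))
    )
    g = (
        1.0 - math.prod((1.0 - η) ** wj for η, wj in zip(choice, w))
        for choice in itertools.product(*(d.g for d in elements))
    )
    return DualHesitantElement(HesitantSet(h), HesitantSet(g))


@dataclass(frozen=True)
class DualHesitantSet:
    """One dual hesitant fuzzy element per label of an ordered universe."""

    universe: tuple[str, ...]
    elements: Mapping[str, DualHesitantElement]

    def __init__(
        self,
        universe: Sequence[str],
        elements: Mapping[str, DualHesitantElement],
    ) -> None:
        labels = tuple(universe)
        if len(set(labels)) != len(labels):
            raise ValidationError("universe labels must be distinct")
        if set(elements) != set(labels):
            missing = set(labels) - set(elements)
            extra = set(elements) - set(labels)
            raise ValidationError(
                f"elements do not match universe (missing {sorted(missing)}, "
                f"extra {sorted(extra)})"
            )
        object.__setattr__(self, "universe", labels)
        object.__setattr__(
            self, "elements", {x: elements[x] for x in labels}
        )

    def __getitem__(self, label: str) -> DualHesitantElement:
        return self.elements[label]

    def __iter__(self) -> Iterator[str]:
        return iter(self.universe)

    @classmethod
    def full(cls, universe: Sequence[str]) -> "DualHesitantSet":
        return cls(universe, {x: FULL_ELEMENT for x in universe})

    @classmethod
    def empty(cls, universe: Sequence[str]) -> "DualHesitantSet":
        return cls(universe, {x: EMPTY_ELEMENT for x in universe})

    def validate_input(self, where: str = "set") -> "DualHesitantSet":
        for x, d in self.elements.items():
            d.validate_input(f"{where}[{x}]")
        return self

    def map(self, fn) -> "DualHesitantSet":
        return DualHesitantSet(
            self.universe, {x: fn(d) for x, d in self.elements.items()}
        )

    def complement(self) -> "DualHesitantSet":
        return self.map(dhfe_complement)

    def _zip(self, other: "DualHesitantSet", fn) -> "DualHesitantSet":
        if self.universe != other.universe:
            raise ValidationError("universe mismatch between DHFSs")
        return DualHesitantSet(
            self.universe,
            {x: fn(self.elements[x], other.elements[x]) for x in self.universe},
        )

    def union(self, other: "DualHesitantSet") -> "DualHesitantSet":
        return self._zip(other, dhfe_union)

    def intersection(self, other: "DualHesitantSet") -> "DualHesitantSet":
        return self._zip(other, dhfe_intersection)


def _hfe_leq(a: HesitantSet, b: HesitantSet) -> bool:
    """σ(k) comparison: every k-th largest of ``a`` ≤ that of ``b``."""
    n = max(len(a), len(b))
    return all(x <= y for x, y in zip(a.descending(n), b.descending(n)))


def dhfs_subset(d1: DualHesitantSet, d2: DualHesitantSet) -> bool:
    """Component-wise subset order on DHFSs.

    True iff at every label the memberships of ``d1`` are dominated by those
    of ``d2`` and the nonmemberships dominate, compared position-by-position
    after sorting descending and extending the shorter side by repeating its
    smallest value.
    """
    if d1.universe != d2.universe:
        raise ValidationError("universe mismatch between DHFSs")
    return all(
        _hfe_leq(d1[x].h, d2[x].h) and _hfe_leq(d2[x].g, d1[x].g)
        for x in d1.universe
    )
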