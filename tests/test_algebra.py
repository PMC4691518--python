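"""Element-level algebra: canonical form, filtered join/meet, complement,
score, ⊕ and the DHFA/DHFG aggregation operators."""

import itertools
import math
import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dhfrough import (
    DualHesitantElement,
    DualHesitantSet,
    HesitantSet,
    ValidationError,
    dhfa,
    dhfe_compare,
    dhfe_complement,
    dhfe_intersection,
    dhfe_oplus,
    dhfe_score,
    dhfe_union,
    dhfg,
    dhfs_subset,
    hfe_join,
    hfe_meet,
    normalize_hfe,
)
from dhfrough.algebra import EMPTY_ELEMENT, EMPTY_HFE, FULL_ELEMENT

# grades on a coarse grid keep hypothesis cases exact in float arithmetic
grades = st.integers(0, 10).map(lambda k: k / 10)
hfes = st.lists(grades, min_size=1, max_size=4).map(HesitantSet)
dhfes = st.builds(DualHesitantElement, hfes, hfes)


def H(*values):
    return HesitantSet(values)


class TestNormalize:
    @pytest.mark.parametrize(
        "raw, expected",
        [
            ((0.3, 0.3, 0.1), (0.1, 0.3)),
            ((0.6,), (0.6,)),
            ((0.4, 0.3), (0.3, 0.4)),
        ],
    )
    def test_sorts_and_dedups(self, raw, expected):
        assert normalize_hfe(raw).values == expected

    def test_idempotent(self):
        once = normalize_hfe((0.5, 0.2, 0.5))
        assert normalize_hfe(once.values) == once

    def test_rejects_out_of_range(self):
        with pytest.raises(ValidationError, match="1.2"):
            normalize_hfe((0.3, 1.2))


class TestJoinMeet:
    def test_join_example(self):
        assert hfe_join(H(0.1, 0.4, 0.5), H(0.2, 0.3, 0.4)) == H(
            0.2, 0.3, 0.4, 0.5
        )

    def test_meet_example(self):
        assert hfe_meet(H(0.1, 0.4, 0.5), H(0.2, 0.3, 0.4)) == H(
            0.1, 0.2, 0.3, 0.4
        )

    def test_three_way_meet_matches_expert_fusion_cell(self):
        # the optimistic-upper aggregation across three experts at one label
        assert hfe_meet(H(0.6, 0.7), H(0.7, 0.8), H(0.5, 0.7)) == H(
            0.5, 0.6, 0.7
        )

    def test_three_way_join(self):
        assert hfe_join(H(0.4, 0.6), H(0.5, 0.6), H(0.5, 0.6)) == H(0.5, 0.6)

    @given(hfes)
    def test_idempotent(self, h):
        assert hfe_join(h, h) == h
        assert hfe_meet(h, h) == h

    def test_empty_operands_rejected(self):
        with pytest.raises(ValidationError):
            hfe_join()
        with pytest.raises(ValidationError):
            hfe_meet(H(0.2), EMPTY_HFE)

    @given(st.lists(hfes, min_size=2, max_size=4))
    @settings(max_examples=60)
    def test_nary_equals_every_pairwise_fold_order(self, operands):
        """The n-ary closed form is the same as folding the binary
        operation pairwise, whatever the argument order."""
        for op in (hfe_join, hfe_meet):
            expected = op(*operands)
            for perm in itertools.permutations(operands):
                folded = perm[0]
                for nxt in perm[1:]:
                    folded = op(folded, nxt)
                assert folded == expected

    @given(st.lists(hfes, min_size=1, max_size=4))
    def test_bounds(self, operands):
        assert hfe_join(*operands).lower == max(h.lower for h in operands)
        assert hfe_meet(*operands).upper == min(h.upper for h in operands)


class TestUnionIntersectionComplement:
    def test_union(self, example_pair):
        d1, d2 = example_pair
        assert dhfe_union(d1, d2) == DualHesitantElement.of(
            (0.2, 0.3, 0.4, 0.5), (0.2, 0.3)
        )

    def test_intersection(self, example_pair):
        d1, d2 = example_pair
        assert dhfe_intersection(d1, d2) == DualHesitantElement.of(
            (0.1, 0.2, 0.3, 0.4), (0.4, 0.5)
        )

    @given(dhfes)
    def test_union_intersection_idempotent(self, d):
        assert dhfe_union(d, d) == d
        assert dhfe_intersection(d, d) == d

    def test_complement_swaps_parts(self, example_pair):
        d1, _ = example_pair
        assert dhfe_complement(d1) == DualHesitantElement.of(
            (0.2, 0.3), (0.1, 0.4, 0.5)
        )

    @given(dhfes)
    def test_double_complement(self, d):
        assert dhfe_complement(dhfe_complement(d)) == d

    def test_membership_only_branch(self):
        d = DualHesitantElement(H(0.3, 0.6), EMPTY_HFE)
        c = dhfe_complement(d)
        assert c.h == H(0.4, 0.7) and not c.g

    def test_nonmembership_only_branch(self):
        d = DualHesitantElement(EMPTY_HFE, H(0.2))
        c = dhfe_complement(d)
        assert not c.h and c.g == H(0.8)

    def test_both_empty_rejected(self):
        with pytest.raises(ValidationError):
            dhfe_complement(DualHesitantElement(EMPTY_HFE, EMPTY_HFE))


class TestScoreAndCompare:
    @pytest.mark.parametrize(
        "h, g, expected",
        [
            ((1,), (0,), 1.0),
            ((0,), (1,), -1.0),
            ((0.7, 0.8), (0.2, 0.3), 0.5),
            ((0.4, 0.6), (0.2, 0.3), 0.25),
            ((0.51,), (0.36,), 0.15),
        ],
    )
    def test_values(self, h, g, expected):
        assert dhfe_score(DualHesitantElement.of(h, g)) == pytest.approx(
            expected
        )

    @given(dhfes)
    def test_range(self, d):
        assert -1.0 <= dhfe_score(d) <= 1.0

    def test_compare_orders_the_documented_pair(self):
        d1 = DualHesitantElement.of((0.7, 0.8), (0.2, 0.3))
        d2 = DualHesitantElement.of((0.4, 0.6), (0.2, 0.3))
        assert dhfe_compare(d1, d2) == "succeeds"
        assert dhfe_compare(d2, d1) == "precedes"

    def test_compare_equal_scores(self):
        a = DualHesitantElement.of((0.6,), (0.1,))
        b = DualHesitantElement.of((0.7,), (0.2,))
        assert dhfe_compare(a, b) == "equivalent"
        assert dhfe_compare(a, a) == "equivalent"

    def test_score_requires_full_pair(self):
        with pytest.raises(ValidationError):
            dhfe_score(DualHesitantElement(H(0.3), EMPTY_HFE))


def _shifted(ds: DualHesitantSet, delta: float) -> DualHesitantSet:
    """Pointwise enlargement: memberships pulled toward 1, nonmemberships
    scaled toward 0.  Affine maps are injective, so hesitancy cardinalities
    are preserved and the σ(k) comparison dominates position by position."""
    return ds.map(
        lambda d: DualHesitantElement.of(
            (v + delta * (1.0 - v) for v in d.h),
            (v * (1.0 - delta) for v in d.g),
        )
    )


class TestSubsetOrder:
    def _random_dhfs(self, rng, labels=("a", "b", "c")):
        def elem():
            h = [rng.choice(range(11)) / 10 for _ in range(rng.randint(1, 3))]
            g = [rng.choice(range(11)) / 10 for _ in range(rng.randint(1, 3))]
            return DualHesitantElement.of(h, g)

        return DualHesitantSet(labels, {x: elem() for x in labels})

    def test_reflexive_and_empty_below_full(self):
        labels = ("a", "b")
        empty = DualHesitantSet.empty(labels)
        full = DualHesitantSet.full(labels)
        assert dhfs_subset(empty, empty)
        assert dhfs_subset(empty, full)
        assert not dhfs_subset(full, empty)

    def test_partial_order_on_shifted_chains(self):
        rng = random.Random(42)
        for _ in range(30):
            d0 = self._random_dhfs(rng)
            d1 = _shifted(d0, 0.1)
            d2 = _shifted(d1, 0.2)
            assert dhfs_subset(d0, d1) and dhfs_subset(d1, d2)
            assert dhfs_subset(d0, d2)  # transitivity along the chain

    def test_antisymmetry_on_canonical_forms(self):
        rng = random.Random(7)
        for _ in range(30):
            d1 = self._random_dhfs(rng)
            d2 = self._random_dhfs(rng)
            if dhfs_subset(d1, d2) and dhfs_subset(d2, d1):
                for x in d1.universe:
                    n = max(len(d1[x].h), len(d2[x].h))
                    assert d1[x].h.descending(n) == d2[x].h.descending(n)
                    m = max(len(d1[x].g), len(d2[x].g))
                    assert d1[x].g.descending(m) == d2[x].g.descending(m)

    def test_universe_mismatch(self):
        with pytest.raises(ValidationError):
            dhfs_subset(
                DualHesitantSet.full(("a",)), DualHesitantSet.full(("b",))
            )


class TestOplus:
    def test_singleton_cell(self):
        d = DualHesitantElement.of((0.3,), (0.6,))
        assert dhfe_oplus(d, d) == DualHesitantElement.of((0.51,), (0.36,))

    def test_multivalued_cell(self):
        lower = DualHesitantElement.of((0.4, 0.5), (0.3, 0.4))
        upper = DualHesitantElement.of((0.4, 0.5), (0.2,))
        assert dhfe_oplus(lower, upper) == DualHesitantElement.of(
            (0.64, 0.7, 0.75), (0.06, 0.08)
        )

    @given(dhfes)
    def test_identity(self, d):
        assert dhfe_oplus(d, EMPTY_ELEMENT) == d

    @given(dhfes, dhfes, dhfes)
    @settings(max_examples=60)
    def test_commutative_and_associative(self, a, b, c):
        assert dhfe_oplus(a, b) == dhfe_oplus(b, a)
        assert dhfe_oplus(dhfe_oplus(a, b), c) == dhfe_oplus(
            a, dhfe_oplus(b, c)
        )


class TestAggregation:
    def test_idempotent_on_identical_singletons(self):
        d = DualHesitantElement.of((0.4,), (0.3,))
        for op in (dhfa, dhfg):
            out = op([d, d, d])
            assert out.h.values == pytest.approx((0.4,))
            assert out.g.values == pytest.approx((0.3,))

    def test_geometric_pair(self):
        a = DualHesitantElement.of((0.4,), (0.2,))
        b = DualHesitantElement.of((0.9,), (0.1,))
        out = dhfg([a, b])
        assert out.h.values == pytest.approx((0.6,))
        assert out.g.values == pytest.approx((1 - math.sqrt(0.72),))

    def test_averaging_pair(self):
        a = DualHesitantElement.of((0.4,), (0.2,))
        b = DualHesitantElement.of((0.9,), (0.1,))
        out = dhfa([a, b])
        assert out.h.values == pytest.approx((1 - math.sqrt(0.06),))
        assert out.g.values == pytest.approx((math.sqrt(0.02),))

    def test_weight_validation(self):
        d = DualHesitantElement.of((0.4,), (0.3,))
        with pytest.raises(ValidationError):
            dhfa([d, d], weights=(0.5,))
        with pytest.raises(ValidationError):
            dhfg([d, d], weights=(0.9, 0.2))
        with pytest.raises(ValidationError):
            dhfa([])

    def test_custom_weights(self):
        a = DualHesitantElement.of((0.4,), (0.2,))
        b = DualHesitantElement.of((0.9,), (0.1,))
        out = dhfg([a, b], weights=(1.0, 0.0))
        assert out.h.values == pytest.approx((0.4,))
        assert out.g.values == pytest.approx((0.2,))


class TestDhfsLaws:
    """Set-level laws induced by the element operations."""

    def _pair(self, seed):
        rng = random.Random(seed)
        labels = ("a", "b", "c")

        def elem():
            h = [rng.choice(range(11)) / 10 for _ in range(rng.randint(1, 3))]
            g = [rng.choice(range(11)) / 10 for _ in range(rng.randint(1, 3))]
            return DualHesitantElement.of(h, g)

        return tuple(
            DualHesitantSet(labels, {x: elem() for x in labels})
            for _ in range(3)
        )

    @pytest.mark.parametrize("seed", range(15))
    def test_de_morgan_commutativity_associativity_distributivity(self, seed):
        d1, d2, d3 = self._pair(seed)
        assert d1.union(d2).complement() == d1.complement().intersection(
            d2.complement()
        )
        assert d1.intersection(d2).complement() == d1.complement().union(
            d2.complement()
        )
        assert d1.union(d2) == d2.union(d1)
        assert d1.intersection(d2) == d2.intersection(d1)
        assert d1.union(d2.union(d3)) == d1.union(d2).union(d3)
        assert d1.intersection(d2.intersection(d3)) == d1.intersection(
            d2
        ).intersection(d3)

    def test_distributivity_fails_under_value_filtering(self):
        """The filtered union/intersection are NOT mutually distributive:
        filtering pools candidate grades across operands, and a grade
        eliminated inside a nested operation can survive when the
        operations are expanded.  This frozen counterexample documents the
        behaviour (memberships {0.1,0.9}, {0.2}, {0.8}; all
        nonmemberships {0.5})."""
        d1 = DualHesitantElement.of((0.1, 0.9), (0.5,))
        d2 = DualHesitantElement.of((0.2,), (0.5,))
        d3 = DualHesitantElement.of((0.8,), (0.5,))
        nested = dhfe_intersection(d1, dhfe_union(d2, d3))
        expanded = dhfe_union(
            dhfe_intersection(d1, d2), dhfe_intersection(d1, d3)
        )
        assert nested.h == H(0.1, 0.8)
        assert expanded.h == H(0.1, 0.2, 0.8)
        assert nested != expanded
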