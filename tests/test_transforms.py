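"""The transformation catalog: exact values, symmetries, monotonicity."""

import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from symtrans.taxonomy import VariableKind, VariableMeta
from symtrans.transforms import (
    LADDER,
    DomainError,
    TransformSpec,
    amount_transform,
    apply,
    bounded_amount_transform,
    bounded_count_transform,
    count_transform,
    counted_fraction_logit,
    default_start,
    difference_transform,
    fraction_transform,
    identity_spec,
    ladder_powers,
    ordinal_scores,
    power_transform,
    ratio_transform,
    rank_transform,
)

ladder_st = st.sampled_from(LADDER)


class TestLadder:
    def test_eleven_distinct_ascending_rungs(self):
        rungs = ladder_powers()
        assert len(rungs) == 11
        assert rungs == sorted(set(rungs))
        assert rungs[0] == -2 and rungs[-1] == 2
        assert Fraction(0) in rungs and Fraction(1) in rungs
        # every rung really is m/n with n<=3, |m|<=2
        assert all(abs(p.numerator) <= 2 and p.denominator <= 3 for p in rungs)


class TestPowerTransform:
    @pytest.mark.parametrize(
        "x, p, base, expected",
        [
            (4, Fraction(1, 2), math.e, 2.0),
            (100, 0, 10, 2.0),
            (2, -1, math.e, 0.5),  # 1/time is a speed
            (8, Fraction(1, 3), math.e, 2.0),
        ],
    )
    def test_exact_values(self, x, p, base, expected):
        assert power_transform(x, p, base) == pytest.approx(expected, abs=1e-12)

    def test_nonpositive_input_rejected_with_offender(self):
        with pytest.raises(DomainError, match="-3"):
            power_transform([2.0, -3.0], 0)
        with pytest.raises(DomainError):
            power_transform(0.0, -1)

    @given(
        xs=st.lists(st.floats(0.01, 1e4), min_size=2, max_size=30, unique=True),
        p=ladder_st,
    )
    def test_monotone_increasing_for_nonneg_p_decreasing_for_neg(self, xs, p):
        xs = np.sort(np.asarray(xs))
        out = np.asarray(power_transform(xs, p))
        diffs = np.diff(out)
        if p < 0:
            assert (diffs < 0).all()
        else:
            assert (diffs > 0).all()


class TestAmountAndCount:
    def test_amount_at_lower_bound_and_shift(self):
        assert amount_transform(5.0, C=5.0, p=1) == 0.0
        assert amount_transform(9.0, C=5.0, p=Fraction(1, 2)) == pytest.approx(2.0)

    def test_zero_amount_with_start_gives_finite_log(self):
        s = 0.25
        assert amount_transform(0.0, C=0.0, p=0, start=s) == pytest.approx(math.log(s))

    def test_below_lower_bound_rejected(self):
        with pytest.raises(DomainError, match="below lower bound"):
            amount_transform(1.0, C=2.0, p=1)

    def test_count_examples_and_negative_rejection(self):
        assert count_transform(9, Fraction(1, 2)) == pytest.approx(3.0)
        assert count_transform(0, Fraction(1, 2)) == 0.0
        with pytest.raises(DomainError, match="negative"):
            count_transform(-1)

    @pytest.mark.parametrize("lam", [5.0, 12.0])
    def test_sqrt_stabilizes_poisson_variance_near_quarter(self, lam, rng):
        draws = rng.poisson(lam, size=100_000)
        v = np.var(np.asarray(count_transform(draws, Fraction(1, 2))))
        assert v == pytest.approx(0.25, rel=0.15)

    def test_default_start_is_half_min_positive_only_when_needed(self):
        vals = [0.0, 2.0, 6.0]
        assert default_start(vals, Fraction(1, 2)) == 0.0  # p>0 never needs it
        assert default_start(vals, 0) == 1.0               # half of min positive 2
        assert default_start([1.0, 2.0], 0) == 0.0          # no zeros present


class TestRatio:
    def test_log_form_and_base(self):
        assert ratio_transform(8, 2, 0, log_base=2) == pytest.approx(2.0)

    @given(
        x=st.floats(0.01, 1e3), y=st.floats(0.01, 1e3), p=ladder_st
    )
    def test_antisymmetry_in_arguments(self, x, y, p):
        assert ratio_transform(x, y, p) == pytest.approx(
            -ratio_transform(y, x, p), abs=1e-9
        )
        assert ratio_transform(x, x, p) == pytest.approx(0.0, abs=1e-12)

    def test_log_ratio_equals_difference_of_log_amounts(self, rng):
        x, y = rng.lognormal(size=50), rng.lognormal(size=50)
        lhs = ratio_transform(x, y, 0)
        rhs = np.asarray(amount_transform(x, 0.0, 0, 0.0)) - np.asarray(
            amount_transform(y, 0.0, 0, 0.0)
        )
        np.testing.assert_allclose(lhs, rhs, atol=1e-12)


class TestFractionFamily:
    def test_logit_values(self):
        assert fraction_transform(0.5, 0) == 0.0
        assert fraction_transform(0.25, 0) == pytest.approx(math.log(1 / 3))

    def test_boundary_with_logit_is_instructive_domain_error(self):
        with pytest.raises(DomainError, match="start"):
            fraction_transform(0.0, 0)

    @given(r=st.floats(0.001, 0.999), p=ladder_st)
    def test_complement_antisymmetry(self, r, p):
        assert fraction_transform(r, p) == pytest.approx(
            -fraction_transform(1 - r, p), rel=1e-9, abs=1e-9
        )

    def test_counted_fraction_started_logit(self):
        assert counted_fraction_logit(5, 10) == 0.0
        assert counted_fraction_logit(0, 1) == pytest.approx(math.log(0.25))
        n = np.arange(0, 41)
        np.testing.assert_allclose(
            counted_fraction_logit(n, 40), -counted_fraction_logit(40 - n, 40),
            atol=1e-12,
        )
        with pytest.raises(DomainError):
            counted_fraction_logit(5, 4)

    def test_bounded_amount_as_fraction(self):
        a, b = 3.0, 11.0
        assert bounded_amount_transform((a + b) / 2, a, b, 0) == 0.0
        assert bounded_amount_transform(a, a, b, 1) == -1.0  # folded power 0-1
        # scale-free: affine recoding leaves the transform unchanged
        y = np.linspace(a, b, 9)
        t1 = bounded_amount_transform(y, a, b, Fraction(1, 2))
        t2 = bounded_amount_transform(10 * y + 5, 10 * a + 5, 10 * b + 5,
                                      Fraction(1, 2))
        np.testing.assert_allclose(t1, t2, atol=1e-12)

    def test_bounded_count_exact_formula(self):
        assert bounded_count_transform(15, 0, 30) == 0.0
        assert bounded_count_transform(0, 0, 30) == pytest.approx(math.log(1 / 91))
        n = np.arange(0, 31)
        np.testing.assert_allclose(
            bounded_count_transform(n, 0, 30),
            -np.asarray(bounded_count_transform(30 - n, 0, 30)),
            atol=1e-12,
        )

    def test_rank_is_bounded_count_on_1_to_N(self):
        assert rank_transform(1, 3) == pytest.approx(math.log(1 / 7))
        assert rank_transform(2, 3) == 0.0  # mid rank of odd N
        np.testing.assert_allclose(
            rank_transform(np.arange(1, 8), 7),
            bounded_count_transform(np.arange(1, 8), 1, 7),
        )


class TestOrdinalScores:
    def test_two_equal_categories(self):
        np.testing.assert_allclose(
            ordinal_scores([50, 50]),
            [math.log(0.25 / 0.75), math.log(0.75 / 0.25)],
        )

    def test_uniform_four_categories(self):
        expected = [math.log(p / (1 - p)) for p in (0.125, 0.375, 0.625, 0.875)]
        np.testing.assert_allclose(ordinal_scores([10, 10, 10, 10]), expected)

    @given(
        counts=st.lists(st.integers(1, 100), min_size=2, max_size=8)
    )
    def test_reversal_antisymmetry_and_monotonicity(self, counts):
        s = ordinal_scores(counts)
        np.testing.assert_allclose(s, -ordinal_scores(counts[::-1])[::-1], atol=1e-9)
        assert (np.diff(s) > 0).all()

    def test_all_zero_counts_rejected(self):
        with pytest.raises(DomainError, match="zero"):
            ordinal_scores([0, 0, 0])


class TestDifference:
    def test_identical_components_give_zero(self):
        spec = TransformSpec(kind=VariableKind.AMOUNT, power=Fraction(1, 2))
        x = np.array([1.0, 4.0, 9.0])
        np.testing.assert_allclose(difference_transform(x, x, spec, spec), 0.0)

    def test_log_components_coincide_with_log_ratio(self, rng):
        spec = TransformSpec(kind=VariableKind.AMOUNT, power=Fraction(0))
        x, y = rng.lognormal(size=20), rng.lognormal(size=20)
        np.testing.assert_allclose(
            difference_transform(x, y, spec, spec), ratio_transform(x, y, 0),
            atol=1e-12,
        )

    def test_difference_components_cannot_recurse(self):
        spec = TransformSpec(kind=VariableKind.DIFFERENCE, power=Fraction(1, 2))
        with pytest.raises(DomainError, match="difference"):
            difference_transform([1.0], [2.0], spec, spec)


class TestTransformSpec:
    @given(
        p=ladder_st,
        lower=st.one_of(st.none(), st.floats(-50, 50)),
        const=st.floats(0, 2),
        reverse=st.booleans(),
    )
    def test_serialization_roundtrip_is_bit_identical(self, p, lower, const, reverse):
        spec = TransformSpec(
            kind=VariableKind.AMOUNT, power=p, lower=lower,
            additive_constant=const, reverse=reverse,
        )
        text = spec.serialize()
        assert TransformSpec.deserialize(text) == spec
        assert TransformSpec.deserialize(text).serialize() == text

    def test_off_ladder_power_rejected(self):
        with pytest.raises(ValueError, match="ladder"):
            TransformSpec(kind=VariableKind.AMOUNT, power=Fraction(3, 4))

    def test_negative_constant_rejected(self):
        with pytest.raises(ValueError):
            TransformSpec(kind=VariableKind.COUNT, additive_constant=-0.1)


class TestApply:
    def meta_and_series(self, rng, n=60):
        meta = VariableMeta(name="v", kind=VariableKind.AMOUNT)
        return meta, pd.Series(rng.lognormal(size=n), name="v")

    def test_identity_spec_is_passthrough(self, rng):
        meta, s = self.meta_and_series(rng)
        out = apply(s, meta, identity_spec(meta.kind))
        pd.testing.assert_series_equal(out, s, check_names=False)

    def test_reverse_negates_after_transformation(self, rng):
        meta, s = self.meta_and_series(rng)
        spec = TransformSpec(kind=VariableKind.AMOUNT, power=Fraction(0))
        fwd = apply(s, meta, spec)
        rev = apply(s, meta, TransformSpec(kind=VariableKind.AMOUNT,
                                           power=Fraction(0), reverse=True))
        np.testing.assert_allclose(rev.to_numpy(), -fwd.to_numpy())

    def test_missing_values_stay_missing(self, rng):
        meta, s = self.meta_and_series(rng)
        s.iloc[[3, 7]] = np.nan
        out = apply(s, meta, TransformSpec(kind=VariableKind.AMOUNT,
                                           power=Fraction(1, 2)))
        assert out.isna().tolist() == s.isna().tolist()

    @given(p=ladder_st)
    def test_monotonicity_direction_by_sign_of_power(self, p):
        rng = np.random.default_rng(7)
        meta = VariableMeta(name="v", kind=VariableKind.AMOUNT)
        s = pd.Series(np.sort(rng.lognormal(size=25)), name="v")
        spec = TransformSpec(kind=VariableKind.AMOUNT, power=p)
        out = apply(s, meta, spec).to_numpy()
        if p < 0:
            assert (np.diff(out) < 0).all()
        else:
            assert (np.diff(out) > 0).all()

    def test_log_spec_is_invertible_to_high_precision(self, rng):
        meta, s = self.meta_and_series(rng)
        spec = TransformSpec(kind=VariableKind.AMOUNT, power=Fraction(0))
        out = apply(s, meta, spec)
        back = np.exp(out.to_numpy())
        np.testing.assert_allclose(back, s.to_numpy(), rtol=1e-12)

    def test_domain_error_names_variable(self, rng):
        meta = VariableMeta(name="ecog", kind=VariableKind.FRACTION)
        s = pd.Series([0.5, 0.0, 0.7], name="ecog")
        with pytest.raises(DomainError, match="ecog"):
            apply(s, meta, TransformSpec(kind=VariableKind.FRACTION, power=Fraction(0)))

    def test_kind_mismatch_rejected(self, rng):
        meta, s = self.meta_and_series(rng)
        with pytest.raises(ValueError, match="kind"):
            apply(s, meta, TransformSpec(kind=VariableKind.COUNT, power=Fraction(1, 2)))

    def test_ordinal_apply_uses_scores(self):
        meta = VariableMeta(name="sev", kind=VariableKind.ORDINAL,
                            category_order=["lo", "mid", "hi"])
        s = pd.Series(["lo"] * 25 + ["mid"] * 50 + ["hi"] * 25, name="sev")
        out = apply(s, meta, TransformSpec(kind=VariableKind.ORDINAL,
                                           power=Fraction(0)))
        # 25/50/25 split: mid-proportion logits at 0.125, 0.5, 0.875
        assert out.iloc[0] == pytest.approx(math.log(0.125 / 0.875))
        assert out.iloc[30] == pytest.approx(0.0)
        assert out.iloc[-1] == pytest.approx(math.log(0.875 / 0.125))
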