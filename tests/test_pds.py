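"""Core polynomial arithmetic: canonical form, evaluation, interpolation,
composition."""

import math

import pytest
import sympy
from hypothesis import given, settings, strategies as st

from polydyn.pds import (
    PDS,
    FieldSpec,
    Polynomial,
    all_states,
    canonicalize,
    interpolate_table,
    state_from_string,
    state_to_string,
)

from conftest import F2, F3, const, random_pds, random_polynomial, x


class TestCanonicalForm:
    @pytest.mark.parametrize(
        "terms, field, expected_terms",
        [
            ({(2,): 1}, F2, {(1,): 1}),  # x^2 = x on F_2
            ({(1,): 2}, F2, {}),  # x + x = 0 in char 2
            ({(0, 4): 1}, F3, {(0, 2): 1}),  # x^4 = x^2 on F_3
            ({(3,): 1}, F3, {(1,): 1}),  # x^3 = x on F_3
            ({(1,): 1, (2,): 1}, F2, {}),  # x + x^2 = 0 on F_2
        ],
    )
    def test_reduction_examples(self, terms, field, expected_terms):
        n = len(next(iter(terms)))
        assert Polynomial(terms, n, field).terms == expected_terms

    def test_canonicalize_idempotent_and_function_preserving(self, rng):
        field = F3
        for _ in range(20):
            n = rng.randint(1, 4)
            raw = {
                tuple(rng.randint(0, 6) for _ in range(n)): rng.randint(1, 8)
                for _ in range(rng.randint(1, 6))
            }
            poly = Polynomial(raw, n, field)
            assert canonicalize(poly) == poly
            # canonical form evaluates identically to the raw term map
            for s in all_states(n, field):
                raw_val = sum(
                    c * math.prod(v**e for v, e in zip(s, exps))
                    for exps, c in raw.items()
                ) % field.p
                assert poly.evaluate(s) == raw_val

    def test_equality_is_functional_equality(self):
        # x1*(x1+1) is the zero function on F_2
        p = x(1, 1) * (x(1, 1) + 1)
        assert p.is_zero
        # OR written two ways
        a, b = x(1, 2), x(2, 2)
        assert a + b + a * b == b + a + b * a


class TestEvaluation:
    def test_identity(self):
        sys2 = PDS.identity(2, F2)
        assert sys2.evaluate((1, 0)) == (1, 0)

    def test_direct_substitution(self):
        sysm = PDS([x(2, 2), x(1, 2) * x(2, 2)], F2)
        assert sysm.evaluate((1, 0)) == (0, 0)

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            PDS.identity(2, F2).evaluate((1, 0, 1))


class TestInterpolation:
    @pytest.mark.parametrize(
        "table, expected",
        [
            (  # Boolean AND
                {(0, 0): 0, (0, 1): 0, (1, 0): 0, (1, 1): 1},
                {(1, 1): 1},
            ),
            (  # Boolean OR -> x1 + x2 + x1*x2
                {(0, 0): 0, (0, 1): 1, (1, 0): 1, (1, 1): 1},
                {(1, 0): 1, (0, 1): 1, (1, 1): 1},
            ),
        ],
    )
    def test_boolean_gates(self, table, expected):
        assert interpolate_table(table, F2).terms == expected

    def test_incomplete_table_rejected(self):
        with pytest.raises(ValueError, match="incomplete"):
            interpolate_table({(0,): 1}, F2)

    @pytest.mark.parametrize("field", [F2, F3, FieldSpec(5)])
    def test_roundtrip_function_polynomial_bijection(self, field, rng):
        for _ in range(10):
            n = rng.randint(1, 3)
            g = random_polynomial(rng, n, field)
            table = {s: g.evaluate(s) for s in all_states(n, field)}
            assert interpolate_table(table, field) == g

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(
        p=st.sampled_from([2, 3]),
        n=st.integers(1, 3),
        data=st.data(),
    )
    def test_any_function_has_unique_canonical_polynomial(self, p, n, data):
        """Interpolating an arbitrary table and re-tabulating is lossless."""
        field = FieldSpec(p)
        points = list(all_states(n, field))
        values = data.draw(
            st.lists(
                st.integers(0, p - 1), min_size=len(points), max_size=len(points)
            )
        )
        table = dict(zip(points, values))
        g = interpolate_table(table, field)
        assert {s: g.evaluate(s) for s in points} == table

    def test_embedding_into_larger_ring(self):
        # AND of x2, x4 inside a 5-variable ring
        table = {(0, 0): 0, (0, 1): 0, (1, 0): 0, (1, 1): 1}
        g = interpolate_table(table, F2, nvars=5, on_vars=[2, 4])
        assert g.support == frozenset({2, 4})
        assert g.evaluate((0, 1, 0, 1, 0)) == 1
        assert g.evaluate((1, 1, 0, 0, 1)) == 0


class TestComposition:
    def test_negation_is_involution(self, negation1):
        assert negation1.compose(2) == PDS.identity(1, F2)

    def test_identity_composes_to_identity(self):
        ident = PDS.identity(3, F3)
        for m in (1, 2, 5):
            assert ident.compose(m) == ident

    def test_swap_squares_to_identity(self):
        swap = PDS([x(2, 2), x(1, 2)], F2)
        sq = swap.compose(2)
        assert sq == PDS.identity(2, F2)
        for s in all_states(2, F2):
            assert sq.evaluate(s) == swap.evaluate(swap.evaluate(s))

    def test_compose_one_is_self(self, rotation3):
        assert rotation3.compose(1) == rotation3

    def test_compose_rejects_nonpositive(self, rotation3):
        with pytest.raises(ValueError):
            rotation3.compose(0)

    @pytest.mark.parametrize("field,n", [(F2, 4), (F3, 3), (FieldSpec(5), 2)])
    def test_compose_matches_iterated_evaluation(self, field, n, rng):
        for _ in range(5):
            sysm = random_pds(rng, n, field)
            m = rng.randint(1, 4)
            fm = sysm.compose(m)
            for s in all_states(n, field):
                assert fm.evaluate(s) == sysm.iterate(s, m)


class TestSympyCrossCheck:
    """Independent oracle: our ring arithmetic agrees with sympy's symbolic
    expansion over GF(p), compared as functions on F_p^n."""

    @pytest.mark.parametrize("p", [2, 3, 5])
    def test_product_matches_sympy(self, p, rng):
        field = FieldSpec(p)
        n = 3 if p == 2 else 2
        xs = sympy.symbols(f"y1:{n + 1}")

        def to_sympy(poly):
            return sum(
                int(c) * sympy.prod(v**e for v, e in zip(xs, exps))
                for exps, c in poly.terms.items()
            )

        for _ in range(5):
            a = random_polynomial(rng, n, field)
            b = random_polynomial(rng, n, field)
            ours = a * b
            theirs = sympy.expand(to_sympy(a) * to_sympy(b))
            for s in all_states(n, field):
                want = int(theirs.subs(dict(zip(xs, s)))) % p
                assert ours.evaluate(s) == want


class TestStateStrings:
    def test_roundtrip_convention(self):
        s = state_from_string("010", F2)
        assert s == (0, 1, 0)  # x1 leftmost
        assert state_to_string(s) == "010"

    def test_digit_out_of_range(self):
        with pytest.raises(ValueError):
            state_from_string("021", F2)
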