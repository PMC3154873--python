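"""Boolean/logical-model conversion and sequential update schedules."""

import random
from itertools import product

import pytest

from polydyn.conversion import (
    LogicalTable,
    Schedule,
    VariableTable,
    boolean_rules_to_pds,
    boolean_to_polynomial,
    extend_multivalued,
    is_continuous,
    out_of_range_states,
    sequential_compose,
)
from polydyn.parse import ParseError, parse_boolean_expr
from polydyn.pds import PDS, all_states
from polydyn.solver import steady_states

from conftest import F2, F3, random_pds, x


def _truth(ast, assignment):
    """Direct Boolean semantics of the AST: the conversion oracle."""
    op = ast[0]
    if op == "const":
        return ast[1]
    if op == "var":
        return assignment[ast[1]]
    if op == "not":
        return 1 - _truth(ast[1], assignment)
    a = _truth(ast[1], assignment)
    b = _truth(ast[2], assignment)
    return a and b if op == "and" else (a or b)


class TestBooleanToPolynomial:
    @pytest.mark.parametrize(
        "expr, n, expected",
        [
            ("x1 AND x2", 2, {(1, 1): 1}),
            ("NOT x1", 1, {(1,): 1, (0,): 1}),
            ("x1 & x2", 2, {(1, 1): 1}),
            ("~x1", 1, {(1,): 1, (0,): 1}),
        ],
    )
    def test_primitive_encodings(self, expr, n, expected):
        assert boolean_to_polynomial(expr, n).terms == expected

    @pytest.mark.parametrize(
        "expr, n",
        [
            ("(x1 OR x2) AND NOT x3", 3),
            ("NOT (x1 AND (x2 OR NOT x3))", 3),
            ("x1 OR x2 OR x3 OR x4", 4),
            ("not x1 and not x2", 2),
            ("x1 | x2 & !x3", 3),
        ],
    )
    def test_truth_table_preserved(self, expr, n):
        poly = boolean_to_polynomial(expr, n)
        ast = parse_boolean_expr(expr)
        for s in all_states(n, F2):
            assignment = {i + 1: v for i, v in enumerate(s)}
            assert poly.evaluate(s) == _truth(ast, assignment)

    def test_truth_tables_random_expressions(self, rng):
        """Exhaustive preservation for randomly built expressions, n <= 6."""

        def build(depth, n):
            if depth == 0 or rng.random() < 0.3:
                return f"x{rng.randint(1, n)}"
            op = rng.choice(["AND", "OR", "NOT"])
            if op == "NOT":
                return f"NOT ({build(depth - 1, n)})"
            return f"({build(depth - 1, n)}) {op} ({build(depth - 1, n)})"

        for _ in range(25):
            n = rng.randint(2, 6)
            expr = build(3, n)
            poly = boolean_to_polynomial(expr, n)
            ast = parse_boolean_expr(expr)
            for s in all_states(n, F2):
                assignment = {i + 1: v for i, v in enumerate(s)}
                assert poly.evaluate(s) == _truth(ast, assignment)

    def test_parse_error_has_position(self):
        with pytest.raises(ParseError, match="column"):
            boolean_to_polynomial("x1 AND", 2)


def table5_model():
    """Boolean x1 driving a 3-level x2 (the low/medium/high switch)."""
    x2_rows = {
        (0, 0): 0, (0, 1): 1, (0, 2): 2,  # x1 absent: x2 holds its level
        (1, 0): 1, (1, 1): 2, (1, 2): 2,  # x1 present: x2 steps up
    }
    return LogicalTable(
        max_levels=(1, 2),
        tables=[
            VariableTable([1], {(0,): 0, (1,): 1}),  # x1 holds itself
            VariableTable([1, 2], x2_rows),
        ],
    )


class TestMultivaluedExtension:
    def test_extension_row_repeats_last_defined_row(self):
        pds = extend_multivalued(table5_model(), 3)
        f2 = pds.functions[1]
        # all 9 cells: rows x1 = 0,1 as declared, row x1 = 2 copies x1 = 1
        expected = {
            (0, 0): 0, (0, 1): 1, (0, 2): 2,
            (1, 0): 1, (1, 1): 2, (1, 2): 2,
            (2, 0): 1, (2, 1): 2, (2, 2): 2,
        }
        for (a, b), want in expected.items():
            assert f2.evaluate((a, b)) == want
        # the worked entry: x1 present, x2 low -> medium
        assert f2.evaluate((1, 0)) == 1

    def test_all_variables_already_full_range_is_identity_extension(self, rng):
        rows = {
            (a, b): rng.randrange(3)
            for a, b in product(range(3), repeat=2)
        }
        lt = LogicalTable(
            (2, 2),
            [
                VariableTable([1, 2], rows),
                VariableTable([2], {(0,): 0, (1,): 1, (2,): 2}),
            ],
        )
        pds = extend_multivalued(lt, 3)
        for combo, want in rows.items():
            assert pds.functions[0].evaluate(combo) == want

    def test_boolean_system_extended_to_p3_agrees_on_boolean_states(self, rng):
        """Restricted to {0,1}^n the embedded dynamics match the original."""
        for _ in range(5):
            n = rng.randint(2, 4)
            bool_sys = random_pds(rng, n, F2)
            tables = []
            for i, f in enumerate(bool_sys.functions, start=1):
                rows = {
                    s: f.evaluate(s) for s in all_states(n, F2)
                }
                tables.append(VariableTable(list(range(1, n + 1)), rows))
            lt = LogicalTable((1,) * n, tables)
            ext = extend_multivalued(lt, 3)
            for s in all_states(n, F2):
                assert ext.evaluate(s) == bool_sys.evaluate(s)

    def test_p_too_small_rejected(self):
        with pytest.raises(ValueError, match="too small"):
            extend_multivalued(table5_model(), 2)

    def test_out_of_range_states_flagged(self):
        lt = table5_model()
        flagged = out_of_range_states(lt, [(2, 1), (1, 2), (0, 0)])
        assert flagged == [(2, 1)]

    def test_incomplete_table_rejected(self):
        with pytest.raises(ValueError, match="cover"):
            LogicalTable((1,), [VariableTable([1], {(0,): 0})])


class TestSequentialUpdates:
    def test_identity_any_schedule(self):
        ident = PDS.identity(3, F2)
        for order in ([1, 2, 3], [3, 1, 2], [2, 3, 1]):
            assert sequential_compose(ident, order) == ident

    @pytest.mark.parametrize(
        "order, expected_funcs",
        [
            ([1, 2], lambda: (x(2, 2), x(2, 2))),  # x1'=x2 then x2'=x1'=x2
            ([2, 1], lambda: (x(1, 2), x(1, 2))),  # symmetric
        ],
    )
    def test_swap_system_sweeps(self, order, expected_funcs):
        swap = PDS([x(2, 2), x(1, 2)], F2)
        assert sequential_compose(swap, order).functions == expected_funcs()

    def test_sweep_matches_stepwise_simulation(self, rng):
        for _ in range(10):
            n = rng.randint(2, 5)
            sysm = random_pds(rng, n, F2)
            order = list(range(1, n + 1))
            rng.shuffle(order)
            seq = sequential_compose(sysm, order)
            for s in all_states(n, F2):
                cur = list(s)
                for i in order:
                    cur[i - 1] = sysm.functions[i - 1].evaluate(cur)
                assert seq.evaluate(s) == tuple(cur)

    def test_fixed_points_schedule_invariant(self, rng):
        """Steady states do not depend on the update schedule."""
        for _ in range(8):
            field = rng.choice([F2, F3])
            n = rng.randint(2, 5 if field.p == 2 else 3)
            sysm = random_pds(rng, n, field)
            order = list(range(1, n + 1))
            rng.shuffle(order)
            seq = sequential_compose(sysm, order)
            assert steady_states(seq) == steady_states(sysm)

    def test_invalid_permutation_rejected(self):
        with pytest.raises(ValueError, match="permutation"):
            Schedule([1, 1, 2])


class TestContinuity:
    def test_boolean_systems_are_continuous(self, rng):
        assert is_continuous(random_pds(rng, 3, F2))

    def test_jumping_logical_model_is_not(self):
        # f(x1) = 2*x1^2 + ... : 0 -> 2 jumps two levels over F_3
        from polydyn.pds import interpolate_table

        f = interpolate_table({(0,): 2, (1,): 1, (2,): 0}, F3)
        assert not is_continuous(PDS([f], F3))
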