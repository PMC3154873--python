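"""Translate Boolean rules, multi-valued logical tables and update schedules
into canonical polynomial dynamical systems.

The Boolean encoding over F_2 is the classical one (NOT a = a+1,
a AND b = a*b, a OR b = a+b+a*b).  Multi-valued logical models whose
variables have different maximum levels are embedded in a common prime field
F_p by extending each coordinate's transition table: out-of-range input
levels repeat the last defined row (per input variable, independently) and
outputs are clamped to the target variable's own maximum.  The extra states
exist only to make the algebra work; attractors that touch them should be
flagged as embedding artifacts, not biology.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from itertools import product
from typing import Mapping, Sequence

from .parse import ast_to_polynomial, ast_variables, parse_boolean_expr
from .pds import PDS, FieldSpec, Polynomial, all_states, interpolate_table

__all__ = [
    "BooleanRuleSet",
    "LogicalTable",
    "VariableTable",
    "Schedule",
    "boolean_to_polynomial",
    "boolean_rules_to_pds",
    "extend_multivalued",
    "sequential_compose",
    "is_continuous",
    "out_of_range_states",
]


@dataclass(frozen=True)
class BooleanRuleSet:
    """Ordered Boolean update rules, one expression string per variable."""

    rules: tuple

    def __init__(self, rules: Sequence[str]) -> None:
        object.__setattr__(self, "rules", tuple(rules))

    @property
    def nvars(self) -> int:
        return len(self.rules)


@dataclass(frozen=True)
class VariableTable:
    """Transition table of one variable of a multi-valued logical model.

    ``inputs`` are the 1-based indices the variable listens to; ``rows``
    maps input tuples (levels of the input variables, in order) to the next
    level of this variable.
    """

    inputs: tuple
    rows: Mapping[tuple, int]

    def __init__(self, inputs: Sequence[int], rows: Mapping[tuple, int]) -> None:
        object.__setattr__(self, "inputs", tuple(inputs))
        object.__setattr__(self, "rows", dict(rows))


@dataclass(frozen=True)
class LogicalTable:
    """Multi-valued logical model: per-variable max levels and tables."""

    max_levels: tuple  # max level of each variable (levels are 0..max)
    tables: tuple  # one VariableTable per variable

    def __init__(
        self, max_levels: Sequence[int], tables: Sequence[VariableTable]
    ) -> None:
        ml = tuple(max_levels)
        tb = tuple(tables)
        if len(ml) != len(tb):
            raise ValueError("one table per variable required")
        for i, t in enumerate(tb):
            for j in t.inputs:
                if not 1 <= j <= len(ml):
                    raise ValueError(f"table {i + 1} references variable x{j}")
            expected = 1
            for j in t.inputs:
                expected *= ml[j - 1] + 1
            if len(t.rows) != expected:
                raise ValueError(
                    f"table for x{i + 1} must cover all {expected} input "
                    f"combinations, got {len(t.rows)}"
                )
            for combo, out in t.rows.items():
                for lvl, j in zip(combo, t.inputs):
                    if not 0 <= lvl <= ml[j - 1]:
                        raise ValueError(
                            f"table for x{i + 1}: input level {lvl} out of "
                            f"range for x{j}"
                        )
                if not 0 <= out <= ml[i]:
                    raise ValueError(
                        f"table for x{i + 1}: output level {out} exceeds "
                        f"max level {ml[i]}"
                    )
        object.__setattr__(self, "max_levels", ml)
        object.__setattr__(self, "tables", tb)

    @property
    def nvars(self) -> int:
        return len(self.max_levels)


@dataclass(frozen=True)
class Schedule:
    """Sequential update order: a permutation of 1..n."""

    ordering: tuple

    def __init__(self, ordering: Sequence[int]) -> None:
        order = tuple(ordering)
        if sorted(order) != list(range(1, len(order) + 1)):
            raise ValueError(f"not a permutation of 1..{len(order)}: {order}")
        object.__setattr__(self, "ordering", order)


def boolean_to_polynomial(
    expr: str, nvars: int, alias: Mapping[str, int] | None = None
) -> Polynomial:
    """Convert one Boolean expression to its canonical F_2 polynomial."""
    field = FieldSpec(2)
    ast = parse_boolean_expr(expr, alias=alias)
    return ast_to_polynomial(ast, nvars, field)


def boolean_rules_to_pds(rules: BooleanRuleSet | Sequence[str]) -> PDS:
    """Convert an ordered Boolean rule set to a PDS over F_2."""
    if isinstance(rules, BooleanRuleSet):
        exprs = rules.rules
    else:
        exprs = tuple(rules)
    field = FieldSpec(2)
    asts = [parse_boolean_expr(e, line=i + 1) for i, e in enumerate(exprs)]
    n = len(exprs)
    maxvar = max((max(ast_variables(a), default=0) for a in asts), default=0)
    if maxvar > n:
        raise ValueError(
            f"rule references x{maxvar} but only {n} rules are given"
        )
    return PDS([ast_to_polynomial(a, n, field) for a in asts], field)


def extend_multivalued(tables: LogicalTable, p: int) -> PDS:
    """Embed a multi-valued logical model in F_p by table extension.

    For each coordinate, inputs above a variable's maximum level are clamped
    to that maximum (i.e. the last defined row/column is repeated), and the
    resulting output is clamped to the coordinate's own maximum level.  The
    extended tables are then interpolated to canonical polynomials.
    """
    field = FieldSpec(p)  # validates primality
    if p < max(tables.max_levels) + 1:
        raise ValueError(
            f"p={p} too small: some variable has {max(tables.max_levels) + 1} levels"
        )
    n = tables.nvars
    functions = []
    for i, t in enumerate(tables.tables):
        if not t.inputs:
            # constant coordinate
            functions.append(
                Polynomial.constant(t.rows[()], n, field)
            )
            continue
        full = {}
        caps = [tables.max_levels[j - 1] for j in t.inputs]
        own_max = tables.max_levels[i]
        for combo in product(range(p), repeat=len(t.inputs)):
            clamped = tuple(min(v, c) for v, c in zip(combo, caps))
            out = t.rows[clamped]
            full[combo] = min(out, own_max)  # repeat-then-clamp
        functions.append(
            interpolate_table(full, field, nvars=n, on_vars=list(t.inputs))
        )
    return PDS(functions, field)


def out_of_range_states(tables: LogicalTable, states) -> list:
    """States (tuples) containing a level above some variable's maximum.

    Attractors of the embedded PDS that contain such states are artifacts of
    the field extension and should be ignored when interpreting dynamics.
    """
    flagged = []
    for s in states:
        if any(v > m for v, m in zip(s, tables.max_levels)):
            flagged.append(tuple(s))
    return flagged


def sequential_compose(system: PDS, schedule: Schedule | Sequence[int]) -> PDS:
    """Synchronous PDS equivalent to one sequential sweep in schedule order.

    Variables are updated one at a time; rules of later variables see the
    already-updated values of earlier ones.  The result F satisfies
    F(x) = (state after the full sweep), so iterating F reproduces the
    sequential dynamics sampled once per sweep.
    """
    if not isinstance(schedule, Schedule):
        schedule = Schedule(schedule)
    n = system.nvars
    if len(schedule.ordering) != n:
        raise ValueError(
            f"schedule length {len(schedule.ordering)} != system dimension {n}"
        )
    field = system.field
    # current[j] = polynomial (in the original state) for the value of x_j
    current = [Polynomial.variable(j, n, field) for j in range(1, n + 1)]
    for i in schedule.ordering:
        current[i - 1] = system.functions[i - 1].substitute(current)
    return PDS(current, field)


def is_continuous(system: PDS) -> bool:
    """Whether no variable ever changes by more than one level per step.

    Logical-model semantics (GINsim-style) require updates to move a variable
    at most one unit towards its target; Boolean systems are trivially
    continuous.  Checked exhaustively, so intended for small state spaces.
    """
    for s in all_states(system.nvars, system.field):
        nxt = system.evaluate(s)
        if any(abs(a - b) > 1 for a, b in zip(s, nxt)):
            return False
    return True
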