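"""Model file readers/writers, DOT emission and JSON reports.

Formats (all plain text, one rule per line, ``#`` comments allowed):

* polynomial:      ``fi = <expr>`` with ``+ - * ^``, variables ``x1..xn``
* boolean:         ``fi = <expr>`` with NOT/AND/OR (aliases ``! ~ & |``)
* probabilistic:   repeated ``fi = <expr> # prob`` lines per coordinate;
  probabilities optional (uniform when omitted for a coordinate)
* logical table:   a ``levels:`` header with per-variable maximum levels,
  then one block per variable: ``fi: <input vars>`` followed by
  whitespace-separated rows ``<input levels...> <output level>``

The number of variables is inferred from the largest f/x index; coordinates
without a declared rule default to the identity update x_i.  State strings
read left to right as x1..xn.  An optional alias table maps external names
(e.g. gene symbols) to ``x_i``; internally everything is an index.
"""

from __future__ import annotations

import json
import re
from fractions import Fraction
from typing import Mapping, Sequence

import networkx as nx

from .conversion import LogicalTable, VariableTable, extend_multivalued
from .parse import (
    ParseError,
    ast_to_polynomial,
    ast_variables,
    parse_boolean_expr,
    parse_polynomial_expr,
)
from .pds import (
    PDS,
    FieldSpec,
    Polynomial,
    state_to_string,
)
from .probabilistic import ProbabilisticPDS
from .solver import CycleSet, Trajectory

__all__ = [
    "parse_model",
    "parse_polynomial_system",
    "parse_boolean_system",
    "parse_probabilistic_system",
    "parse_logical_table",
    "parse_alias_table",
    "write_pds",
    "write_probabilistic",
    "dot_wiring_diagram",
    "dot_phase_space",
    "dot_trajectory",
    "cycle_set_report",
    "REPORT_SCHEMA_VERSION",
]

REPORT_SCHEMA_VERSION = 1

_RULE_RE = re.compile(r"^\s*[fF](\d+)\s*=\s*(.*?)\s*$")


def _iter_rule_lines(text: str):
    """Yield (lineno, f-index, rhs, prob-or-None), skipping blanks/comments."""
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        prob = None
        if "#" in line:
            line, _, tail = line.partition("#")
            tail = tail.strip()
            if tail:
                try:
                    prob = Fraction(tail)
                except ValueError as exc:
                    raise ParseError(
                        f"invalid probability {tail!r}", lineno
                    ) from exc
        m = _RULE_RE.match(line)
        if m is None:
            raise ParseError(
                f"expected 'fi = <expression>', got {line.strip()!r}", lineno
            )
        idx = int(m.group(1))
        if idx < 1:
            raise ParseError("function index must be >= 1", lineno)
        yield lineno, idx, m.group(2), prob


def _infer_nvars(rule_asts: Mapping[int, object]) -> int:
    n = max(rule_asts, default=0)
    for ast in rule_asts.values():
        refs = ast_variables(ast)
        if refs:
            n = max(n, max(refs))
    return n


def parse_polynomial_system(
    text: str, p: int, alias: Mapping[str, int] | None = None
) -> PDS:
    field = FieldSpec(p)
    asts: dict = {}
    for lineno, idx, rhs, prob in _iter_rule_lines(text):
        if prob is not None:
            raise ParseError("probabilities not allowed in a deterministic model", lineno)
        if idx in asts:
            raise ParseError(f"duplicate rule for f{idx}", lineno)
        asts[idx] = parse_polynomial_expr(rhs, line=lineno, alias=alias)
    if not asts:
        raise ParseError("model file contains no rules")
    n = _infer_nvars(asts)
    functions = []
    for i in range(1, n + 1):
        if i in asts:
            functions.append(ast_to_polynomial(asts[i], n, field))
        else:
            functions.append(Polynomial.variable(i, n, field))
    return PDS(functions, field)


def parse_boolean_system(
    text: str, alias: Mapping[str, int] | None = None
) -> PDS:
    field = FieldSpec(2)
    asts: dict = {}
    for lineno, idx, rhs, prob in _iter_rule_lines(text):
        if prob is not None:
            raise ParseError("probabilities not allowed in a deterministic model", lineno)
        if idx in asts:
            raise ParseError(f"duplicate rule for f{idx}", lineno)
        asts[idx] = parse_boolean_expr(rhs, line=lineno, alias=alias)
    if not asts:
        raise ParseError("model file contains no rules")
    n = _infer_nvars(asts)
    functions = []
    for i in range(1, n + 1):
        if i in asts:
            functions.append(ast_to_polynomial(asts[i], n, field))
        else:
            functions.append(Polynomial.variable(i, n, field))
    return PDS(functions, field)


def parse_probabilistic_system(
    text: str, p: int, alias: Mapping[str, int] | None = None
) -> ProbabilisticPDS:
    field = FieldSpec(p)
    asts: dict = {}
    probs: dict = {}
    for lineno, idx, rhs, prob in _iter_rule_lines(text):
        asts.setdefault(idx, []).append(parse_polynomial_expr(rhs, line=lineno, alias=alias))
        probs.setdefault(idx, []).append(prob)
    if not asts:
        raise ParseError("model file contains no rules")
    n = max(asts)
    for ast_list in asts.values():
        for a in ast_list:
            refs = ast_variables(a)
            if refs:
                n = max(n, max(refs))
    rules = []
    distributions = []
    for i in range(1, n + 1):
        if i in asts:
            coord = [ast_to_polynomial(a, n, field) for a in asts[i]]
            pr = probs[i]
            if all(q is None for q in pr):
                dist = None
            elif any(q is None for q in pr):
                raise ParseError(
                    f"coordinate f{i}: give probabilities for all rules or none"
                )
            else:
                dist = pr
        else:
            coord = [Polynomial.variable(i, n, field)]
            dist = None
        rules.append(coord)
        distributions.append(dist)
    if all(d is None for d in distributions):
        return ProbabilisticPDS(rules, field)
    full = [
        d if d is not None else [Fraction(1, len(r))] * len(r)
        for d, r in zip(distributions, rules)
    ]
    return ProbabilisticPDS(rules, field, full)


def parse_logical_table(text: str) -> LogicalTable:
    lines = text.splitlines()
    max_levels = None
    tables: dict = {}
    current = None  # (index, inputs, rows)
    for lineno, raw in enumerate(lines, start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if line.lower().startswith("levels:"):
            if max_levels is not None:
                raise ParseError("duplicate levels header", lineno)
            try:
                max_levels = tuple(int(t) for t in line.split(":", 1)[1].split())
            except ValueError as exc:
                raise ParseError("levels header must list integers", lineno) from exc
            if not max_levels or any(m < 1 for m in max_levels):
                raise ParseError("each variable needs a max level >= 1", lineno)
            continue
        m = re.match(r"^[fF](\d+)\s*:\s*(.*)$", line)
        if m:
            if max_levels is None:
                raise ParseError("levels header must come first", lineno)
            idx = int(m.group(1))
            try:
                inputs = [
                    int(t.lstrip("xX")) for t in m.group(2).split()
                ]
            except ValueError as exc:
                raise ParseError("inputs must be variables like x1", lineno) from exc
            if idx in tables:
                raise ParseError(f"duplicate table for f{idx}", lineno)
            current = (idx, inputs, {})
            tables[idx] = current
            continue
        if current is None:
            raise ParseError("row outside of a table block", lineno)
        try:
            nums = [int(t) for t in line.split()]
        except ValueError as exc:
            raise ParseError("table rows must be integers", lineno) from exc
        idx, inputs, rows = current
        if len(nums) != len(inputs) + 1:
            raise ParseError(
                f"row needs {len(inputs)} input levels and one output", lineno
            )
        rows[tuple(nums[:-1])] = nums[-1]
    if max_levels is None:
        raise ParseError("missing levels header")
    n = len(max_levels)
    var_tables = []
    for i in range(1, n + 1):
        if i not in tables:
            raise ParseError(f"missing table for f{i}")
        _, inputs, rows = tables[i]
        var_tables.append(VariableTable(inputs, rows))
    return LogicalTable(max_levels, var_tables)


def parse_alias_table(text: str) -> dict:
    """Lines ``name = xi`` (or ``name xi``) mapping external names to indices."""
    alias: dict = {}
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        parts = re.split(r"[=\s]+", line)
        if len(parts) != 2:
            raise ParseError("expected 'name = xi'", lineno)
        name, target = parts
        m = re.fullmatch(r"[xX](\d+)", target)
        if not m:
            raise ParseError(f"alias target must be like x3, got {target!r}", lineno)
        alias[name] = int(m.group(1))
    return alias


def parse_model(
    path: str,
    fmt: str,
    p: int = 2,
    alias: Mapping[str, int] | None = None,
):
    """Read a model file; returns a PDS (or ProbabilisticPDS for ``prob``).

    ``fmt`` is one of ``poly``, ``bool``, ``table``, ``prob``.  For ``table``
    the logical model is embedded over F_p (p must cover every level).
    """
    with open(path) as fh:
        text = fh.read()
    if fmt == "poly":
        return parse_polynomial_system(text, p, alias)
    if fmt == "bool":
        if p != 2:
            raise ValueError("Boolean models require p = 2")
        return parse_boolean_system(text, alias)
    if fmt == "prob":
        return parse_probabilistic_system(text, p, alias)
    if fmt == "table":
        return extend_multivalued(parse_logical_table(text), p)
    raise ValueError(f"unknown model format {fmt!r}")


# ---- writers -----------------------------------------------------------


def write_pds(system: PDS) -> str:
    """Canonical polynomial text form; parses back to an equal system."""
    return "\n".join(
        f"f{i} = {f}" for i, f in enumerate(system.functions, start=1)
    ) + "\n"


def write_probabilistic(pp: ProbabilisticPDS) -> str:
    lines = []
    for i, (coord, probs) in enumerate(
        zip(pp.rules, pp.probabilities), start=1
    ):
        for f, q in zip(coord, probs):
            lines.append(f"f{i} = {f} # {q}")
    return "\n".join(lines) + "\n"


# ---- DOT emission ------------------------------------------------------


def _dot_quote(s: str) -> str:
    return '"' + s.replace('"', r"\"") + '"'


def dot_wiring_diagram(
    wd: nx.DiGraph, names: Mapping[int, str] | None = None
) -> str:
    """Wiring diagram as DOT: + edges normal, - edges tee, non-unate dashed."""
    names = names or {}
    lines = ["digraph wiring {"]
    for v in sorted(wd.nodes):
        lines.append(f"  {v} [label={_dot_quote(names.get(v, f'x{v}'))}];")
    for u, v, data in sorted(wd.edges(data=True)):
        sign = data.get("sign", "unknown")
        if sign == 1:
            attrs = "arrowhead=normal"
        elif sign == -1:
            attrs = "arrowhead=tee"
        elif sign is None:
            attrs = "arrowhead=normal, style=dashed"
        else:
            attrs = "arrowhead=vee"
        lines.append(f"  {u} -> {v} [{attrs}];")
    lines.append("}")
    return "\n".join(lines) + "\n"


def dot_phase_space(graph: nx.DiGraph, weighted: bool = False) -> str:
    lines = ["digraph phase_space {", "  node [shape=box];"]
    for s in sorted(graph.nodes):
        lines.append(f"  {_dot_quote(state_to_string(s))};")
    for u, v, data in sorted(graph.edges(data=True)):
        label = ""
        if weighted and "weight" in data:
            label = f" [label={_dot_quote(str(data['weight']))}]"
        lines.append(
            f"  {_dot_quote(state_to_string(u))} -> {_dot_quote(state_to_string(v))}{label};"
        )
    lines.append("}")
    return "\n".join(lines) + "\n"


def dot_trajectory(traj: Trajectory) -> str:
    lines = ["digraph trajectory {", "  node [shape=box];"]
    states = list(traj.states)
    for a, b in zip(states, states[1:]):
        lines.append(
            f"  {_dot_quote(state_to_string(a))} -> {_dot_quote(state_to_string(b))};"
        )
    if traj.attractor:
        first_attr = traj.attractor[0]
        lines.append(
            f"  {_dot_quote(state_to_string(traj.attractor[-1]))} -> "
            f"{_dot_quote(state_to_string(first_attr))};"
        )
    lines.append("}")
    return "\n".join(lines) + "\n"


# ---- JSON report -------------------------------------------------------


def cycle_set_report(cs: CycleSet) -> dict:
    return {
        "steady_states": [state_to_string(s) for s in cs.steady_states],
        "limit_cycles": [
            {"period": period, "states": [state_to_string(s) for s in orbit]}
            for period, orbit in cs.cycles
        ],
        "searched_length": cs.searched_length,
    }
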