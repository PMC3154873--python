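"""Recursive-descent parsers for polynomial and Boolean rule expressions.

Polynomial grammar (over F_p): ``+ - * ^``, integer coefficients,
parentheses, variables ``x1..xn``.  Multiplication requires an explicit
``*``.  Boolean grammar: ``NOT/AND/OR`` (case-insensitive) or the aliases
``! ~ & |``, parentheses, constants ``0``/``1``.  XOR is not a primitive.

Both parsers produce a small AST; :func:`ast_to_polynomial` lowers it to a
canonical :class:`~polydyn.pds.Polynomial` once the number of variables and
the field are known (variable indices are collected file-wide first).
"""

from __future__ import annotations

import re
from typing import Mapping, Sequence

from .pds import FieldSpec, Polynomial

__all__ = [
    "ParseError",
    "parse_polynomial_expr",
    "parse_boolean_expr",
    "ast_to_polynomial",
    "ast_variables",
]


class ParseError(ValueError):
    """Syntax error; carries 1-based line/column when known."""

    def __init__(self, message: str, line: int | None = None, col: int | None = None):
        self.line = line
        self.col = col
        loc = ""
        if line is not None and col is not None:
            loc = f" at line {line}, column {col}"
        elif line is not None:
            loc = f" at line {line}"
        elif col is not None:
            loc = f" at column {col}"
        super().__init__(message + loc)


_TOKEN_RE = re.compile(
    r"\s*(?:(?P<int>\d+)|(?P<name>[A-Za-z_][A-Za-z_0-9]*)|(?P<op>[-+*^()!~&|]))"
)

_BOOL_WORDS = {"and", "or", "not", "true", "false"}


class _Tokens:
    def __init__(self, text: str, line: int | None, alias: Mapping[str, int] | None):
        self.text = text
        self.line = line
        self.alias = alias or {}
        self.toks: list[tuple[str, object, int]] = []
        pos = 0
        while pos < len(text):
            m = _TOKEN_RE.match(text, pos)
            if m is None:
                if text[pos:].strip() == "":
                    break
                raise ParseError(
                    f"unexpected character {text[pos:].lstrip()[0]!r}",
                    line,
                    pos + 1,
                )
            pos = m.end()
            if m.group("int") is not None:
                self.toks.append(("int", int(m.group("int")), m.start() + 1))
            elif m.group("name") is not None:
                self.toks.append(("name", m.group("name"), m.start() + 1))
            else:
                self.toks.append(("op", m.group("op"), m.start() + 1))
        self.i = 0

    def peek(self):
        return self.toks[self.i] if self.i < len(self.toks) else ("eof", None, len(self.text) + 1)

    def next(self):
        t = self.peek()
        self.i += 1
        return t

    def expect_op(self, op: str):
        kind, val, col = self.next()
        if kind != "op" or val != op:
            raise ParseError(f"expected {op!r}", self.line, col)

    def error(self, msg: str):
        _, _, col = self.peek()
        raise ParseError(msg, self.line, col)

    def var_index(self, name: str, col: int) -> int:
        if name in self.alias:
            return self.alias[name]
        m = re.fullmatch(r"[xX](\d+)", name)
        if m:
            idx = int(m.group(1))
            if idx < 1:
                raise ParseError(f"variable index must be >= 1: {name}", self.line, col)
            return idx
        raise ParseError(f"unknown variable {name!r}", self.line, col)


# ---- polynomial expressions -------------------------------------------


def parse_polynomial_expr(
    text: str,
    line: int | None = None,
    alias: Mapping[str, int] | None = None,
):
    """Parse an arithmetic expression; returns an AST tuple."""
    tk = _Tokens(text, line, alias)
    ast = _p_sum(tk)
    if tk.peek()[0] != "eof":
        tk.error(f"unexpected token {tk.peek()[1]!r}")
    return ast


def _p_sum(tk: _Tokens):
    kind, val, _ = tk.peek()
    negate = False
    if kind == "op" and val in "+-":
        tk.next()
        negate = val == "-"
    node = _p_term(tk)
    if negate:
        node = ("neg", node)
    while True:
        kind, val, _ = tk.peek()
        if kind == "op" and val in "+-":
            tk.next()
            rhs = _p_term(tk)
            node = ("add", node, rhs) if val == "+" else ("sub", node, rhs)
        else:
            return node


def _p_term(tk: _Tokens):
    node = _p_power(tk)
    while True:
        kind, val, _ = tk.peek()
        if kind == "op" and val == "*":
            tk.next()
            node = ("mul", node, _p_power(tk))
        elif kind in ("int", "name") or (kind == "op" and val == "("):
            tk.error("missing '*' between factors")
        else:
            return node


def _p_power(tk: _Tokens):
    base = _p_atom(tk)
    kind, val, _ = tk.peek()
    if kind == "op" and val == "^":
        tk.next()
        k2, v2, col = tk.next()
        if k2 != "int":
            raise ParseError("exponent must be a nonnegative integer", tk.line, col)
        return ("pow", base, v2)
    return base


def _p_atom(tk: _Tokens):
    kind, val, col = tk.next()
    if kind == "int":
        return ("const", val)
    if kind == "name":
        return ("var", tk.var_index(val, col))
    if kind == "op" and val == "(":
        node = _p_sum(tk)
        tk.expect_op(")")
        return node
    if kind == "op" and val == "-":
        return ("neg", _p_atom(tk))
    raise ParseError(
        "expected a number, variable or '('"
        + ("" if kind != "eof" else " (expression ends early)"),
        tk.line,
        col,
    )


# ---- Boolean expressions ----------------------------------------------


def parse_boolean_expr(
    text: str,
    line: int | None = None,
    alias: Mapping[str, int] | None = None,
):
    """Parse a NOT/AND/OR expression; returns an AST tuple."""
    tk = _Tokens(text, line, alias)
    ast = _b_or(tk)
    if tk.peek()[0] != "eof":
        tk.error(f"unexpected token {tk.peek()[1]!r}")
    return ast


def _is_word(tok, word: str) -> bool:
    return tok[0] == "name" and tok[1].lower() == word


def _b_or(tk: _Tokens):
    node = _b_and(tk)
    while _is_word(tk.peek(), "or") or (tk.peek()[0] == "op" and tk.peek()[1] == "|"):
        tk.next()
        node = ("or", node, _b_and(tk))
    return node


def _b_and(tk: _Tokens):
    node = _b_not(tk)
    while _is_word(tk.peek(), "and") or (tk.peek()[0] == "op" and tk.peek()[1] == "&"):
        tk.next()
        node = ("and", node, _b_not(tk))
    return node


def _b_not(tk: _Tokens):
    tok = tk.peek()
    if _is_word(tok, "not") or (tok[0] == "op" and tok[1] in "!~"):
        tk.next()
        return ("not", _b_not(tk))
    return _b_atom(tk)


def _b_atom(tk: _Tokens):
    kind, val, col = tk.next()
    if kind == "int":
        if val in (0, 1):
            return ("const", val)
        raise ParseError(f"Boolean constant must be 0 or 1, got {val}", tk.line, col)
    if kind == "name":
        if val.lower() in ("true", "false"):
            return ("const", 1 if val.lower() == "true" else 0)
        if val.lower() in _BOOL_WORDS:
            raise ParseError(f"misplaced keyword {val!r}", tk.line, col)
        return ("var", tk.var_index(val, col))
    if kind == "op" and val == "(":
        node = _b_or(tk)
        tk.expect_op(")")
        return node
    raise ParseError(
        "expected a variable, 0/1 or '('"
        + ("" if kind != "eof" else " (expression ends early)"),
        tk.line,
        col,
    )


# ---- lowering ----------------------------------------------------------


def ast_variables(ast) -> set:
    """All 1-based variable indices referenced by the AST."""
    out: set = set()
    stack = [ast]
    while stack:
        node = stack.pop()
        if node[0] == "var":
            out.add(node[1])
        else:
            stack.extend(n for n in node[1:] if isinstance(n, tuple))
    return out


def ast_to_polynomial(ast, nvars: int, field: FieldSpec) -> Polynomial:
    """Lower an AST to a canonical polynomial.

    Boolean connectives use the standard encoding over F_2:
    NOT a = a+1, a AND b = a*b, a OR b = a+b+a*b.
    """
    op = ast[0]
    if op == "const":
        return Polynomial.constant(ast[1], nvars, field)
    if op == "var":
        if ast[1] > nvars:
            raise ParseError(f"variable x{ast[1]} out of range 1..{nvars}")
        return Polynomial.variable(ast[1], nvars, field)
    if op == "neg":
        return -ast_to_polynomial(ast[1], nvars, field)
    if op == "pow":
        return ast_to_polynomial(ast[1], nvars, field) ** ast[2]
    a = ast_to_polynomial(ast[1], nvars, field)
    if op == "not":
        return a + 1
    b = ast_to_polynomial(ast[2], nvars, field)
    if op == "add":
        return a + b
    if op == "sub":
        return a - b
    if op in ("mul", "and"):
        return a * b
    if op == "or":
        return a + b + a * b
    raise ValueError(f"unknown AST node {op!r}")
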