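"""Exact multivariate polynomial arithmetic over a prime field F_p.

Every function F_p^n -> F_p is represented by a unique polynomial whose
per-variable degree is at most p-1: the canonical representative modulo the
field equations x_i^p - x_i.  All arithmetic here keeps polynomials in that
canonical form, so *syntactic* equality of term maps coincides with equality
as functions on F_p^n.  Downstream modules rely on this: a variable occurs in
the canonical polynomial of an update rule exactly when the rule genuinely
depends on it.

States of an n-variable system are plain tuples of ints in {0..p-1};
``state_to_string``/``state_from_string`` convert to the digit-string
convention (x1 leftmost) used in all reports.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from typing import Iterable, Mapping, Sequence

State = tuple  # length-n tuple of ints in {0..p-1}

__all__ = [
    "FieldSpec",
    "Polynomial",
    "PDS",
    "State",
    "interpolate_table",
    "canonicalize",
    "state_to_string",
    "state_from_string",
    "all_states",
]


def _is_prime(p: int) -> bool:
    if p < 2:
        return False
    if p < 4:
        return True
    if p % 2 == 0:
        return False
    d = 3
    while d * d <= p:
        if p % d == 0:
            return False
        d += 2
    return True


@dataclass(frozen=True)
class FieldSpec:
    """Prime field F_p; p is the number of states per variable."""

    p: int

    def __post_init__(self) -> None:
        if not _is_prime(self.p):
            raise ValueError(f"field order must be prime, got {self.p}")


def _reduce_exp(e: int, p: int) -> int:
    # x^p = x on F_p, hence x^e = x^(((e-1) mod (p-1)) + 1) for e >= 1
    if e == 0:
        return 0
    return (e - 1) % (p - 1) + 1


class Polynomial:
    """Sparse canonical polynomial in n variables over F_p.

    ``terms`` maps exponent tuples (length ``nvars``, entries <= p-1) to
    nonzero coefficients in {1..p-1}.  Instances are treated as immutable.
    """

    __slots__ = ("terms", "nvars", "field")

    def __init__(
        self,
        terms: Mapping[tuple, int],
        nvars: int,
        field: FieldSpec,
        _canonical: bool = False,
    ) -> None:
        p = field.p
        if _canonical:
            tmap = dict(terms)
        else:
            tmap: dict = {}
            for exps, coeff in terms.items():
                if len(exps) != nvars:
                    raise ValueError("exponent vector length != nvars")
                c = coeff % p
                if c == 0:
                    continue
                key = tuple(_reduce_exp(e, p) for e in exps)
                c = (tmap.get(key, 0) + c) % p
                if c:
                    tmap[key] = c
                else:
                    tmap.pop(key, None)
        object.__setattr__(self, "terms", tmap)
        object.__setattr__(self, "nvars", nvars)
        object.__setattr__(self, "field", field)

    def __setattr__(self, name, value):  # pragma: no cover - immutability guard
        raise AttributeError("Polynomial is immutable")

    # ---- constructors -------------------------------------------------

    @classmethod
    def zero(cls, nvars: int, field: FieldSpec) -> "Polynomial":
        return cls({}, nvars, field, _canonical=True)

    @classmethod
    def constant(cls, c: int, nvars: int, field: FieldSpec) -> "Polynomial":
        c %= field.p
        if c == 0:
            return cls.zero(nvars, field)
        return cls({(0,) * nvars: c}, nvars, field, _canonical=True)

    @classmethod
    def variable(cls, i: int, nvars: int, field: FieldSpec) -> "Polynomial":
        """The monomial x_i (1-based index)."""
        if not 1 <= i <= nvars:
            raise ValueError(f"variable index {i} out of range 1..{nvars}")
        exps = [0] * nvars
        exps[i - 1] = 1
        return cls({tuple(exps): 1}, nvars, field, _canonical=True)

    # ---- predicates ---------------------------------------------------

    @property
    def is_zero(self) -> bool:
        return not self.terms

    @property
    def is_constant(self) -> bool:
        return all(all(e == 0 for e in exps) for exps in self.terms)

    def constant_value(self) -> int:
        if not self.is_constant:
            raise ValueError("polynomial is not constant")
        return next(iter(self.terms.values()), 0)

    @property
    def support(self) -> frozenset:
        """1-based indices of variables the function genuinely depends on."""
        vs = set()
        for exps in self.terms:
            for i, e in enumerate(exps):
                if e:
                    vs.add(i + 1)
        return frozenset(vs)

    # ---- arithmetic ---------------------------------------------------

    def _check(self, other: "Polynomial") -> None:
        if self.nvars != other.nvars or self.field.p != other.field.p:
            raise ValueError("polynomials over different rings")

    def __add__(self, other) -> "Polynomial":
        if isinstance(other, int):
            other = Polynomial.constant(other, self.nvars, self.field)
        self._check(other)
        p = self.field.p
        tmap = dict(self.terms)
        for exps, c in other.terms.items():
            nc = (tmap.get(exps, 0) + c) % p
            if nc:
                tmap[exps] = nc
            else:
                tmap.pop(exps, None)
        return Polynomial(tmap, self.nvars, self.field, _canonical=True)

    __radd__ = __add__

    def __neg__(self) -> "Polynomial":
        p = self.field.p
        return Polynomial(
            {e: p - c for e, c in self.terms.items()},
            self.nvars,
            self.field,
            _canonical=True,
        )

    def __sub__(self, other) -> "Polynomial":
        if isinstance(other, int):
            other = Polynomial.constant(other, self.nvars, self.field)
        return self + (-other)

    def __rsub__(self, other) -> "Polynomial":
        return (-self) + other

    def __mul__(self, other) -> "Polynomial":
        if isinstance(other, int):
            other = Polynomial.constant(other, self.nvars, self.field)
        self._check(other)
        p = self.field.p
        tmap: dict = {}
        for e1, c1 in self.terms.items():
            for e2, c2 in other.terms.items():
                key = tuple(_reduce_exp(a + b, p) for a, b in zip(e1, e2))
                c = (tmap.get(key, 0) + c1 * c2) % p
                if c:
                    tmap[key] = c
                else:
                    tmap.pop(key, None)
        return Polynomial(tmap, self.nvars, self.field, _canonical=True)

    __rmul__ = __mul__

    def __pow__(self, k: int) -> "Polynomial":
        if k < 0:
            raise ValueError("negative power")
        out = Polynomial.constant(1, self.nvars, self.field)
        base = self
        while k:
            if k & 1:
                out = out * base
            base = base * base if k > 1 else base
            k >>= 1
        return out

    # ---- evaluation / substitution ------------------------------------

    def __call__(self, state: Sequence[int]) -> int:
        return self.evaluate(state)

    def evaluate(self, state: Sequence[int]) -> int:
        if len(state) != self.nvars:
            raise ValueError("state length != nvars")
        p = self.field.p
        total = 0
        for exps, c in self.terms.items():
            v = c
            for x, e in zip(state, exps):
                if e:
                    v = v * pow(x, e, p) % p
                    if v == 0:
                        break
            total += v
        return total % p

    def assign(self, values: Mapping[int, int]) -> "Polynomial":
        """Partially evaluate: fix x_i = values[i] (1-based) and simplify."""
        if not values:
            return self
        p = self.field.p
        tmap: dict = {}
        for exps, c in self.terms.items():
            coeff = c
            new = list(exps)
            for i, v in values.items():
                e = exps[i - 1]
                if e:
                    coeff = coeff * pow(v % p, e, p) % p
                    new[i - 1] = 0
                    if coeff == 0:
                        break
            if coeff == 0:
                continue
            key = tuple(new)
            nc = (tmap.get(key, 0) + coeff) % p
            if nc:
                tmap[key] = nc
            else:
                tmap.pop(key, None)
        return Polynomial(tmap, self.nvars, self.field, _canonical=True)

    def substitute(self, polys: Sequence["Polynomial"]) -> "Polynomial":
        """Evaluate self at (g_1,...,g_n); the workhorse behind composition."""
        if len(polys) != self.nvars:
            raise ValueError("need one substitution polynomial per variable")
        if not polys and self.is_constant:
            return self
        nv = polys[0].nvars if polys else self.nvars
        field = polys[0].field if polys else self.field
        # cache powers g_i^e, e <= p-1
        pow_cache: dict = {}

        def gpow(i: int, e: int) -> Polynomial:
            key = (i, e)
            if key not in pow_cache:
                pow_cache[key] = polys[i] ** e
            return pow_cache[key]

        out = Polynomial.zero(nv, field)
        for exps, c in self.terms.items():
            term = Polynomial.constant(c, nv, field)
            for i, e in enumerate(exps):
                if e:
                    term = term * gpow(i, e)
                    if term.is_zero:
                        break
            out = out + term
        return out

    def embed(self, nvars: int, var_map: Sequence[int]) -> "Polynomial":
        """Re-index into a ring with ``nvars`` variables.

        ``var_map[k]`` is the 1-based target index of this polynomial's
        variable k+1.
        """
        if len(var_map) != self.nvars:
            raise ValueError("var_map length != nvars")
        tmap = {}
        for exps, c in self.terms.items():
            new = [0] * nvars
            for k, e in enumerate(exps):
                if e:
                    new[var_map[k] - 1] = e
            tmap[tuple(new)] = c
        return Polynomial(tmap, nvars, self.field, _canonical=True)

    # ---- comparison / hashing / printing ------------------------------

    def __eq__(self, other) -> bool:
        if not isinstance(other, Polynomial):
            return NotImplemented
        return (
            self.nvars == other.nvars
            and self.field.p == other.field.p
            and self.terms == other.terms
        )

    def __hash__(self) -> int:
        return hash((self.nvars, self.field.p, frozenset(self.terms.items())))

    def __str__(self) -> str:
        if not self.terms:
            return "0"
        # graded lex, x1 > x2 > ... > xn
        def key(exps):
            return (-sum(exps), tuple(-e for e in exps))

        parts = []
        for exps in sorted(self.terms, key=key):
            c = self.terms[exps]
            factors = []
            for i, e in enumerate(exps):
                if e == 1:
                    factors.append(f"x{i + 1}")
                elif e > 1:
                    factors.append(f"x{i + 1}^{e}")
            if not factors:
                parts.append(str(c))
            elif c == 1:
                parts.append("*".join(factors))
            else:
                parts.append(f"{c}*" + "*".join(factors))
        return " + ".join(parts)

    def __repr__(self) -> str:
        return f"Polynomial({self} over F_{self.field.p}, n={self.nvars})"


def canonicalize(poly: Polynomial) -> Polynomial:
    """Return the canonical representative of ``poly`` mod (x_i^p - x_i).

    Construction keeps polynomials canonical, so this is the identity on any
    ``Polynomial`` already built; it exists as the explicit normal-form entry
    point and re-reduces raw term maps passed through ``Polynomial(...)``.
    """
    return Polynomial(poly.terms, poly.nvars, poly.field)


@dataclass(frozen=True)
class PDS:
    """Polynomial dynamical system f = (f_1,...,f_n): F_p^n -> F_p^n."""

    functions: tuple
    field: FieldSpec

    def __init__(self, functions: Iterable[Polynomial], field: FieldSpec) -> None:
        fns = tuple(functions)
        for f in fns:
            if f.field.p != field.p:
                raise ValueError("coordinate function over wrong field")
            if f.nvars != len(fns):
                raise ValueError("coordinate function has wrong nvars")
        object.__setattr__(self, "functions", fns)
        object.__setattr__(self, "field", field)

    @property
    def nvars(self) -> int:
        return len(self.functions)

    def evaluate(self, state: Sequence[int]) -> State:
        if len(state) != self.nvars:
            raise ValueError(
                f"state length {len(state)} != system dimension {self.nvars}"
            )
        return tuple(f.evaluate(state) for f in self.functions)

    __call__ = evaluate

    def iterate(self, state: Sequence[int], m: int) -> State:
        s = tuple(state)
        for _ in range(m):
            s = self.evaluate(s)
        return s

    def compose(self, m: int) -> "PDS":
        """The m-fold self-composition f^m, coordinatewise canonical."""
        if m < 1:
            raise ValueError("m must be >= 1")
        current = self
        for _ in range(m - 1):
            current = PDS(
                [f.substitute(self.functions) for f in current.functions],
                self.field,
            )
        return current

    @classmethod
    def identity(cls, nvars: int, field: FieldSpec) -> "PDS":
        return cls(
            [Polynomial.variable(i, nvars, field) for i in range(1, nvars + 1)],
            field,
        )


# ---- interpolation -----------------------------------------------------


def _inverse_vandermonde(p: int) -> list:
    """Inverse mod p of the p x p matrix V[a][e] = a^e (Gauss-Jordan)."""
    V = [[pow(a, e, p) for e in range(p)] for a in range(p)]
    inv = [[1 if i == j else 0 for j in range(p)] for i in range(p)]
    for col in range(p):
        piv = next(r for r in range(col, p) if V[r][col] % p)
        V[col], V[piv] = V[piv], V[col]
        inv[col], inv[piv] = inv[piv], inv[col]
        s = pow(V[col][col], -1, p)
        V[col] = [v * s % p for v in V[col]]
        inv[col] = [v * s % p for v in inv[col]]
        for r in range(p):
            if r != col and V[r][col]:
                m = V[r][col]
                V[r] = [(a - m * b) % p for a, b in zip(V[r], V[col])]
                inv[r] = [(a - m * b) % p for a, b in zip(inv[r], inv[col])]
    return inv


_VINV_CACHE: dict = {}


def interpolate_table(
    table: Mapping[tuple, int],
    field: FieldSpec,
    nvars: int | None = None,
    on_vars: Sequence[int] | None = None,
) -> Polynomial:
    """Unique canonical polynomial agreeing with ``table`` on F_p^s.

    ``table`` must map every tuple in {0..p-1}^s to a value.  With
    ``on_vars`` (1-based indices, length s) the result lives in a ring of
    ``nvars`` variables but involves only those s variables — used to embed
    small local truth tables into large systems.

    Lagrange interpolation is applied one axis at a time (values -> univariate
    coefficients via the inverse Vandermonde matrix of F_p), which is
    O(s * p^s * p) instead of expanding p^s indicator products.
    """
    p = field.p
    if not table:
        raise ValueError("empty table")
    s = len(next(iter(table)))
    if on_vars is None:
        on_vars = list(range(1, s + 1))
        if nvars is None:
            nvars = s
    else:
        if nvars is None:
            raise ValueError("nvars required with on_vars")
        if len(on_vars) != s:
            raise ValueError("on_vars length != table arity")
    size = p**s
    if len(table) != size:
        raise ValueError(
            f"incomplete table: expected {size} entries over F_{p}^{s}, "
            f"got {len(table)}"
        )
    if p not in _VINV_CACHE:
        _VINV_CACHE[p] = _inverse_vandermonde(p)
    vinv = _VINV_CACHE[p]

    # mixed-radix dense array, index = sum a_k * p^k (axis 0 fastest)
    arr = [0] * size
    weights = [p**k for k in range(s)]
    for point, val in table.items():
        idx = sum((a % p) * w for a, w in zip(point, weights))
        arr[idx] = val % p

    for axis in range(s):
        w = weights[axis]
        block = w * p
        for base in range(0, size, block):
            for off in range(w):
                start = base + off
                vals = [arr[start + a * w] for a in range(p)]
                for e in range(p):
                    arr[start + e * w] = (
                        sum(vinv[e][a] * vals[a] for a in range(p)) % p
                    )

    terms: dict = {}
    for idx, c in enumerate(arr):
        if c == 0:
            continue
        exps = [0] * nvars
        rem = idx
        for k in range(s):
            rem, e = divmod(rem, p)
            exps[on_vars[k] - 1] = e
        terms[tuple(exps)] = c
    # exponent p-1 can appear; that is canonical already (<= p-1)
    return Polynomial(terms, nvars, field, _canonical=True)


# ---- states ------------------------------------------------------------


def state_to_string(state: Sequence[int]) -> str:
    """Digit string, x1 leftmost — '010' means x1=0, x2=1, x3=0."""
    if any(not 0 <= v <= 9 for v in state):
        raise ValueError("digit-string rendering requires values 0..9")
    return "".join(str(v) for v in state)


def state_from_string(s: str, field: FieldSpec) -> State:
    vals = tuple(int(ch) for ch in s.strip())
    if any(v >= field.p for v in vals):
        raise ValueError(f"state digit out of range for F_{field.p}: {s!r}")
    return vals


def all_states(nvars: int, field: FieldSpec) -> Iterable[State]:
    """All p^n states in lexicographic order (x1 most significant)."""
    return product(range(field.p), repeat=nvars)
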