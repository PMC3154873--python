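import random

import pytest

from polydyn.pds import PDS, FieldSpec, Polynomial, all_states, interpolate_table

F2 = FieldSpec(2)
F3 = FieldSpec(3)


def x(i: int, n: int, field: FieldSpec = F2) -> Polynomial:
    return Polynomial.variable(i, n, field)


def const(c: int, n: int, field: FieldSpec = F2) -> Polynomial:
    return Polynomial.constant(c, n, field)


def random_polynomial(rng: random.Random, n: int, field: FieldSpec) -> Polynomial:
    """Uniformly random function F_p^n -> F_p, via its full table."""
    table = {s: rng.randrange(field.p) for s in all_states(n, field)}
    return interpolate_table(table, field)


def random_pds(rng: random.Random, n: int, field: FieldSpec) -> PDS:
    return PDS([random_polynomial(rng, n, field) for _ in range(n)], field)


@pytest.fixture
def rng():
    return random.Random(20260918)


@pytest.fixture
def rotation3():
    """f = (x3, x1, x2) over F_2: two fixed points and two 3-cycles."""
    return PDS([x(3, 3), x(1, 3), x(2, 3)], F2)


@pytest.fixture
def negation1():
    """f(x1) = x1 + 1 over F_2: the 2-cycle 0 <-> 1."""
    return PDS([x(1, 1) + 1], F2)
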