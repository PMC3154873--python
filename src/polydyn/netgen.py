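"""Random and structured test-network generation.

The generator emulates the sparse regime of biological regulatory networks:
each node listens to a small random set of regulators (truncated Poisson
in-degree, default mean 1.6848 — the average of average in-degrees of the
random benchmark networks) with a uniformly random truth table over those
inputs.  Tables whose interpolated polynomial does not genuinely depend on
every chosen input are redrawn, so all wiring-diagram edges are functional
by construction.

``implant_fixed_points`` plants prescribed steady states by editing each
coordinate's *local* truth table (over its own input set) at the rows the
requested states project to — the scaffolding for completeness checks of
the algebraic solver at sizes where enumeration is impossible.
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass, field as dc_field
from itertools import product
from typing import Sequence

from .pds import PDS, FieldSpec, Polynomial, interpolate_table

__all__ = ["GenSpec", "random_sparse_pds", "conjunctive_random_pds", "implant_fixed_points"]

#: mean in-degree of the sparse benchmark regime
DEFAULT_MEAN_IN_DEGREE = 1.6848


@dataclass(frozen=True)
class GenSpec:
    """Parameters of one generated network; reproducible from ``seed``."""

    n: int
    p: int = 2
    mean_in_degree: float = DEFAULT_MEAN_IN_DEGREE
    max_in_degree: int | None = None  # default: min(4, n)
    rule_family: str = "random-table"  # or "conjunctive"
    implant: tuple = dc_field(default_factory=tuple)  # states to fix
    seed: int = 0

    def __post_init__(self):
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.max_in_degree is None:
            object.__setattr__(self, "max_in_degree", min(4, self.n))
        if self.max_in_degree > self.n:
            raise ValueError("max in-degree exceeds number of variables")
        if self.mean_in_degree < 0:
            raise ValueError("mean in-degree must be >= 0")
        st = tuple(tuple(s) for s in self.implant)
        if len(set(st)) != len(st):
            raise ValueError("implanted states must be pairwise distinct")
        object.__setattr__(self, "implant", st)


def _truncated_poisson(rng: random.Random, mean: float, kmax: int) -> int:
    if mean == 0:
        return 0
    # inverse-CDF on the Poisson pmf, renormalized to 0..kmax
    pmf = []
    for k in range(kmax + 1):
        pmf.append(math.exp(-mean) * mean**k / math.factorial(k))
    total = sum(pmf)
    u = rng.random() * total
    acc = 0.0
    for k, q in enumerate(pmf):
        acc += q
        if u <= acc:
            return k
    return kmax


def _random_functional_table(
    rng: random.Random, inputs: Sequence[int], p: int, n: int, field: FieldSpec
) -> Polynomial:
    """Random table over the inputs whose polynomial depends on all of them."""
    k = len(inputs)
    for _ in range(200):
        table = {
            combo: rng.randrange(p) for combo in product(range(p), repeat=k)
        }
        poly = interpolate_table(table, field, nvars=n, on_vars=list(inputs))
        if poly.support == frozenset(inputs):
            return poly
    raise RuntimeError("could not draw a table depending on all inputs")


def random_sparse_pds(spec: GenSpec) -> PDS:
    """Random sparse PDS per the generation spec (deterministic in the seed)."""
    field = FieldSpec(spec.p)
    rng = random.Random(spec.seed)
    functions = []
    for _ in range(spec.n):
        k = _truncated_poisson(rng, spec.mean_in_degree, spec.max_in_degree)
        inputs = sorted(rng.sample(range(1, spec.n + 1), k))
        if spec.rule_family == "conjunctive" and k > 0:
            exps = [0] * spec.n
            for i in inputs:
                exps[i - 1] = 1
            functions.append(
                Polynomial({tuple(exps): 1}, spec.n, field, _canonical=True)
            )
        elif k == 0:
            functions.append(Polynomial.constant(rng.randrange(spec.p), spec.n, field))
        else:
            functions.append(
                _random_functional_table(rng, inputs, spec.p, spec.n, field)
            )
    system = PDS(functions, field)
    if spec.implant:
        system = implant_fixed_points(system, spec.implant)
    return system


def conjunctive_random_pds(n: int, seed: int, extra_edges: int = 2) -> PDS:
    """Strongly connected conjunctive network: a Hamiltonian cycle plus a few
    random chords, every rule the AND of its in-neighbors."""
    rng = random.Random(seed)
    field = FieldSpec(2)
    perm = list(range(1, n + 1))
    rng.shuffle(perm)
    preds = {i: set() for i in range(1, n + 1)}
    for a, b in zip(perm, perm[1:] + perm[:1]):
        preds[b].add(a)
    for _ in range(extra_edges):
        u = rng.randrange(1, n + 1)
        v = rng.randrange(1, n + 1)
        preds[v].add(u)
    functions = []
    for i in range(1, n + 1):
        exps = [0] * n
        for u in preds[i]:
            exps[u - 1] = 1
        functions.append(Polynomial({tuple(exps): 1}, n, field, _canonical=True))
    return PDS(functions, field)


def implant_fixed_points(system: PDS, states: Sequence[Sequence[int]]) -> PDS:
    """Minimally edit the system so every requested state is a fixed point.

    Each coordinate's local truth table (over its own input set) is edited
    only at the rows the implanted states project to.  When two distinct
    states collide on a coordinate's projection but demand different
    outputs, the input set is enlarged with a variable on which they differ
    before editing, keeping the change local.
    """
    states = [tuple(s) for s in states]
    if len(set(states)) != len(states):
        raise ValueError("implanted states must be pairwise distinct")
    n, field = system.nvars, system.field
    p = field.p
    for s in states:
        if len(s) != n or any(not 0 <= v < p for v in s):
            raise ValueError(f"invalid state {s}")
    if not states:
        return system
    new_functions = []
    for i, f in enumerate(system.functions, start=1):
        inputs = sorted(f.support)
        # grow the input set until no two implanted states collide on it
        # while demanding different outputs of x_i
        while True:
            seen: dict = {}
            conflict = None
            for s in states:
                key = tuple(s[j - 1] for j in inputs)
                if key in seen and seen[key][i - 1] != s[i - 1]:
                    conflict = (seen[key], s)
                    break
                seen.setdefault(key, s)
            if conflict is None:
                break
            a, b = conflict
            diff = next(j for j in range(1, n + 1) if a[j - 1] != b[j - 1])
            inputs = sorted(set(inputs) | {diff})
        # an empty input set means every implanted state demands the same
        # constant; the generic path below handles it (0-ary table)
        table = {
            combo: f.evaluate(_embed(combo, inputs, n))
            for combo in product(range(p), repeat=len(inputs))
        }
        for s in states:
            table[tuple(s[j - 1] for j in inputs)] = s[i - 1]
        new_functions.append(
            interpolate_table(table, field, nvars=n, on_vars=inputs)
        )
    return PDS(new_functions, field)


def _embed(combo: Sequence[int], inputs: Sequence[int], n: int) -> list:
    state = [0] * n
    for v, j in zip(combo, inputs):
        state[j - 1] = v
    return state
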