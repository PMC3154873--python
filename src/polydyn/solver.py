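"""Attractor analysis: steady states, limit cycles, phase space, trajectories.

Steady states of f are the F_p-rational solutions of {f_i(x) - x_i = 0};
states on limit cycles of length m solve f^m(x) = x.  Instead of enumerating
the p^n states, :func:`solve_system` solves such systems exactly by
elimination over the quotient ring F_p[x]/(x_i^p - x_i): repeated unit
propagation of univariate constraints interleaved with branching on the
value of one variable at a time (a characteristic-set / DPLL-style
triangularization).  Working modulo the field equations keeps every ideal
radical and zero-dimensional, so the search is complete — exactly the role
a lexicographic Groebner basis plays in computer-algebra systems — while
exploiting the sparseness typical of biological networks.

For limit cycles of length d >= 2 the system f^d(x) = x is solved in
time-unrolled form: variables z^0..z^{d-1} for the successive states and
sparse equations z^{t+1 mod d}_i = f_i(z^t).  This avoids the dense
polynomials produced by symbolic composition while returning exactly the
periodic points of period dividing d.

Exhaustive phase-space construction remains available for small systems
(p^n up to a configurable threshold) and doubles as the cross-check oracle
for the algebraic route.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from typing import Iterable, Sequence

import networkx as nx

from .pds import PDS, FieldSpec, Polynomial, State, all_states

__all__ = [
    "EquationSystem",
    "CycleSet",
    "Trajectory",
    "StateSpaceTooLarge",
    "solve_system",
    "steady_states",
    "periodic_states",
    "limit_cycles",
    "build_phase_space",
    "attractors_from_phase_space",
    "trajectory",
    "brute_force_attractors",
    "EXHAUSTIVE_THRESHOLD",
]

#: largest p^n for which exhaustive phase-space construction is allowed
EXHAUSTIVE_THRESHOLD = 2**20


class StateSpaceTooLarge(ValueError):
    """Raised when an exhaustive operation is requested above threshold."""


@dataclass(frozen=True)
class EquationSystem:
    """Polynomial equations g = 0 over a common ring."""

    equations: tuple
    field: FieldSpec
    nvars: int

    def __init__(self, equations: Iterable[Polynomial], field: FieldSpec, nvars: int):
        eqs = tuple(equations)
        for g in eqs:
            if g.field.p != field.p or g.nvars != nvars:
                raise ValueError("equation over wrong ring")
        object.__setattr__(self, "equations", eqs)
        object.__setattr__(self, "field", field)
        object.__setattr__(self, "nvars", nvars)


@dataclass(frozen=True)
class CycleSet:
    """Steady states plus limit cycles found up to a searched length.

    ``cycles`` holds (exact_period, states) pairs with the orbit listed in
    transition order starting from its lexicographically smallest state.
    """

    steady_states: tuple
    cycles: tuple
    searched_length: int

    @property
    def all_states(self) -> set:
        out = set(self.steady_states)
        for _, orbit in self.cycles:
            out.update(orbit)
        return out


@dataclass(frozen=True)
class Trajectory:
    """Transient prefix plus the attractor a start state falls into."""

    transient: tuple  # states strictly before the attractor is entered
    attractor: tuple  # the periodic orbit, in transition order
    period: int

    @property
    def states(self) -> tuple:
        return self.transient + self.attractor


# ---- polynomial system solving -----------------------------------------


def _univariate_roots(poly: Polynomial, var: int, p: int) -> list:
    return [v for v in range(p) if poly.assign({var: v}).is_zero]


def solve_system(
    eqs: EquationSystem | Sequence[Polynomial],
    field: FieldSpec | None = None,
    nvars: int | None = None,
) -> list:
    """All common roots in F_p^n of the given equations, sorted.

    Complete and exact: branching assigns field values only, and the field
    equations are implicit in the canonical form, so every root found is
    rational and none is missed.  Variables constrained by no equation are
    free and enumerated last (their count is usually zero in practice).
    """
    if isinstance(eqs, EquationSystem):
        polys, field, nvars = list(eqs.equations), eqs.field, eqs.nvars
    else:
        polys = list(eqs)
        if field is None or nvars is None:
            if not polys:
                raise ValueError("field and nvars required for an empty system")
            field, nvars = polys[0].field, polys[0].nvars
    for g in polys:
        if g.nvars != nvars or g.field.p != field.p:
            raise ValueError("inconsistent equation dimensions")
    p = field.p

    solutions: list = []

    def emit(assignment: dict) -> None:
        # variables not pinned down are genuinely free: every field value
        # extends the partial solution (their equations vanished identically)
        free = [i for i in range(1, nvars + 1) if i not in assignment]
        base = [assignment.get(i, 0) for i in range(1, nvars + 1)]
        if free:
            for combo in product(range(p), repeat=len(free)):
                s = list(base)
                for i, v in zip(free, combo):
                    s[i - 1] = v
                solutions.append(tuple(s))
        else:
            solutions.append(tuple(base))

    def search(active: list, assignment: dict) -> None:
        # --- unit propagation -----------------------------------------
        while True:
            forced: dict = {}
            nxt = []
            ok = True
            for g in active:
                if g.is_zero:
                    continue
                sup = g.support
                if not sup:
                    ok = False  # nonzero constant
                    break
                if len(sup) == 1:
                    (v,) = sup
                    if v in forced:
                        if not g.assign({v: forced[v]}).is_zero:
                            ok = False
                            break
                        continue
                    roots = _univariate_roots(g, v, p)
                    if not roots:
                        ok = False
                        break
                    if len(roots) == 1:
                        forced[v] = roots[0]
                        continue
                nxt.append(g)
            if not ok:
                return
            if not forced:
                active = nxt
                break
            assignment = {**assignment, **forced}
            active = [g.assign(forced) for g in nxt]

        if not active:
            emit(assignment)
            return

        # --- branch ----------------------------------------------------
        # fail-first: smallest-support equation, then most-constrained var
        best = min(active, key=lambda g: (len(g.support), min(g.support)))
        counts: dict = {}
        for g in active:
            for v in g.support:
                counts[v] = counts.get(v, 0) + 1
        var = max(best.support, key=lambda v: (counts[v], -v))
        if len(best.support) == 1:
            values = _univariate_roots(best, var, p)
        else:
            values = range(p)
        for val in values:
            sub = {var: val}
            new_active = []
            consistent = True
            for g in active:
                if var in g.support:
                    g2 = g.assign(sub)
                    if g2.is_zero:
                        continue
                    if not g2.support:  # nonzero constant
                        consistent = False
                        break
                    new_active.append(g2)
                elif not g.is_zero:
                    new_active.append(g)
            if consistent:
                search(new_active, {**assignment, var: val})

    search([g for g in polys if not g.is_zero], {})
    solutions.sort()
    return solutions


def steady_states(system: PDS) -> list:
    """All fixed points f(x) = x, via the algebraic solver; sorted."""
    n, field = system.nvars, system.field
    eqs = [
        f - Polynomial.variable(i + 1, n, field)
        for i, f in enumerate(system.functions)
    ]
    sols = solve_system(eqs, field, n)
    for s in sols:  # cheap safety net; also documents the contract
        assert system.evaluate(s) == s
    return sols


def periodic_states(system: PDS, d: int) -> list:
    """All solutions of f^d(x) = x (period divides d), sorted.

    Solved in unrolled form over n*d variables z^0..z^{d-1} with sparse
    equations f_i(z^t) - z^{t+1 mod d}_i = 0, then projected to z^0.
    """
    if d < 1:
        raise ValueError("cycle length must be >= 1")
    if d == 1:
        return steady_states(system)
    n, field = system.nvars, system.field
    big_n = n * d
    eqs = []
    for t in range(d):
        src = [t * n + i for i in range(1, n + 1)]  # z^t var indices
        tnext = (t + 1) % d
        for i, f in enumerate(system.functions):
            shifted = f.embed(big_n, src)
            eqs.append(shifted - Polynomial.variable(tnext * n + i + 1, big_n, field))
    sols = solve_system(eqs, field, big_n)
    return sorted({s[:n] for s in sols})


def _canonical_orbit(orbit: list) -> tuple:
    k = orbit.index(min(orbit))
    return tuple(orbit[k:] + orbit[:k])


def limit_cycles(system: PDS, m: int) -> CycleSet:
    """Steady states and limit cycles of every exact period up to m.

    For each d = 1..m the periodic points of f^d are computed and grouped
    into orbits by applying f; each orbit is reported once with its exact
    period (which always divides some searched d; every period <= m is
    itself searched, so no short cycle is missed).
    """
    if m < 1:
        raise ValueError("cycle length bound must be >= 1")
    fixed = steady_states(system)
    seen = set(fixed)
    cycles = []
    for d in range(2, m + 1):
        for s in periodic_states(system, d):
            if s in seen:
                continue
            orbit = [s]
            cur = system.evaluate(s)
            while cur != s:
                orbit.append(cur)
                cur = system.evaluate(cur)
            seen.update(orbit)
            cycles.append((len(orbit), _canonical_orbit(orbit)))
    cycles.sort(key=lambda c: (c[0], c[1]))
    return CycleSet(tuple(fixed), tuple(cycles), m)


# ---- exhaustive phase space --------------------------------------------


def build_phase_space(
    system: PDS, threshold: int = EXHAUSTIVE_THRESHOLD
) -> nx.DiGraph:
    """Complete state transition graph (one out-edge per state).

    Refuses above ``threshold`` states; large systems must use the algebraic
    operations instead.
    """
    size = system.field.p**system.nvars
    if size > threshold:
        raise StateSpaceTooLarge(
            f"state space has {size} states (> {threshold}); "
            "use the algebraic steady-state/limit-cycle analysis instead"
        )
    g = nx.DiGraph()
    for s in all_states(system.nvars, system.field):
        g.add_edge(s, system.evaluate(s))
    return g


def attractors_from_phase_space(graph: nx.DiGraph) -> CycleSet:
    """Extract steady states and cycles from an exhaustive transition graph."""
    fixed = []
    cycles = []
    for comp in nx.attracting_components(graph):
        if len(comp) == 1:
            (s,) = comp
            fixed.append(s)
        else:
            start = min(comp)
            orbit = [start]
            cur = next(iter(graph.successors(start)))
            while cur != start:
                orbit.append(cur)
                cur = next(iter(graph.successors(cur)))
            cycles.append((len(orbit), tuple(orbit)))
    fixed.sort()
    cycles.sort(key=lambda c: (c[0], c[1]))
    maxlen = max((c[0] for c in cycles), default=1)
    return CycleSet(tuple(fixed), tuple(cycles), maxlen)


def trajectory(system: PDS, start: Sequence[int]) -> Trajectory:
    """Iterate from ``start`` until a state repeats; split off the attractor."""
    s = tuple(start)
    if len(s) != system.nvars:
        raise ValueError("start state has wrong length")
    seen = {}
    path = []
    while s not in seen:
        seen[s] = len(path)
        path.append(s)
        s = system.evaluate(s)
    k = seen[s]  # first state of the attractor
    return Trajectory(tuple(path[:k]), tuple(path[k:]), len(path) - k)


def brute_force_attractors(system: PDS, max_period: int | None = None) -> CycleSet:
    """Enumeration oracle: attractors by walking every state.

    Independent of the algebraic path; used for cross-checks on small
    systems.  ``max_period`` restricts the report to cycles of that length
    or less (steady states are always included).
    """
    size = system.field.p**system.nvars
    if size > EXHAUSTIVE_THRESHOLD:
        raise StateSpaceTooLarge(f"{size} states is too many to enumerate")
    succ = {s: system.evaluate(s) for s in all_states(system.nvars, system.field)}
    fixed = sorted(s for s, t in succ.items() if s == t)
    cycles = []
    visited = set(fixed)
    for s0 in succ:
        if s0 in visited:
            continue
        index: dict = {}
        chain: list = []
        s = s0
        while s not in visited and s not in index:
            index[s] = len(chain)
            chain.append(s)
            s = succ[s]
        if s in index:  # closed a new cycle
            orbit = chain[index[s]:]
            cycles.append((len(orbit), _canonical_orbit(orbit)))
        visited.update(chain)
    if max_period is not None:
        cycles = [c for c in cycles if c[0] <= max_period]
    cycles.sort(key=lambda c: (c[0], c[1]))
    return CycleSet(
        tuple(fixed), tuple(cycles), max_period or max((c[0] for c in cycles), default=1)
    )
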