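"""Wiring diagrams with functional edges, elementary circuits and signs.

An edge i -> j is *functional* when some state witnesses it: changing only
x_i changes the next value of x_j.  Because update rules are kept in
canonical form modulo the field equations, that is equivalent to x_i
occurring in the canonical polynomial of f_j, so functionality is read off
the support (the witness search is kept as an oracle for tests and for
reporting).

For Boolean systems each functional edge is classified by the discrete
derivative d_i f_j = f_j|_{x_i=1} - f_j|_{x_i=0}: activating (+1) when the
derivative is 0/+ in every context, inhibiting (-1) when 0/-, non-unate when
both strict behaviours occur.  A circuit whose edges are all unate carries
the sign of the product; circuits through a non-unate edge are reported
unsigned, but such an edge can realize either sign in some context, which is
what the multistationarity condition (at least two fixed points require a
realizably positive circuit) relies on.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import product

import networkx as nx

from .pds import PDS, Polynomial

__all__ = [
    "Circuit",
    "functional_wiring_diagram",
    "find_witness",
    "edge_sign",
    "elementary_circuits",
    "functional_circuits",
    "has_positive_circuit",
    "CIRCUIT_CAP",
]

#: default bound on enumerated circuits (counts can grow exponentially)
CIRCUIT_CAP = 10**5


@dataclass(frozen=True)
class Circuit:
    """Elementary circuit with its sign classification.

    ``sign`` is +1/-1 when every edge is unate, ``None`` (unsigned) when the
    circuit passes through a non-unate edge.  ``positive`` flags sign == +1;
    ``can_be_positive`` additionally allows non-unate edges to contribute
    either sign (the reading under which positive circuits are necessary
    for multiple fixed points).
    """

    nodes: tuple  # distinct variables, in traversal order
    edge_signs: tuple = ()  # per-edge +1/-1/None, aligned with nodes

    @property
    def length(self) -> int:
        return len(self.nodes)

    @property
    def sign(self):
        if not self.edge_signs or any(s is None for s in self.edge_signs):
            return None
        prod = 1
        for s in self.edge_signs:
            prod *= s
        return prod

    @property
    def positive(self) -> bool:
        return self.sign == 1

    @property
    def can_be_positive(self) -> bool:
        if not self.edge_signs:
            return False
        if any(s is None for s in self.edge_signs):
            return True  # a non-unate edge can realize either sign
        return self.sign == 1


def functional_wiring_diagram(system: PDS) -> nx.DiGraph:
    """Directed graph on variables 1..n containing only functional edges.

    For Boolean systems every edge carries a ``sign`` attribute
    (+1, -1 or None for non-unate).
    """
    g = nx.DiGraph()
    n = system.nvars
    g.add_nodes_from(range(1, n + 1))
    boolean = system.field.p == 2
    for j, f in enumerate(system.functions, start=1):
        for i in sorted(f.support):
            if boolean:
                g.add_edge(i, j, sign=edge_sign(system, i, j))
            else:
                g.add_edge(i, j)
    return g


def find_witness(system: PDS, i: int, j: int):
    """Exhaustive witness search for edge i -> j, or None.

    Returns a pair of states differing only in x_i on which f_j differs.
    Exponential in n; retained as the definitional oracle for small systems.
    """
    p = system.field.p
    n = system.nvars
    f = system.functions[j - 1]
    others = [k for k in range(1, n + 1) if k != i]
    for ctx in product(range(p), repeat=n - 1):
        vals = {}
        for k, v in zip(others, ctx):
            vals[k] = v
        outs = []
        for a in range(p):
            state = [0] * n
            for k, v in vals.items():
                state[k - 1] = v
            state[i - 1] = a
            outs.append((tuple(state), f.evaluate(state)))
        if len({o for _, o in outs}) > 1:
            # return two states with different next-values of x_j
            seen = {}
            for st, o in outs:
                if seen and o not in seen:
                    return (next(iter(seen.values())), st)
                seen.setdefault(o, st)
    return None


def edge_sign(system: PDS, i: int, j: int) -> int | None:
    """Sign of the functional Boolean edge i -> j: +1, -1 or None (non-unate).

    Computed algebraically from the cofactors d0 = f_j|x_i=0, d1 = f_j|x_i=1:
    an activating context exists iff (1+d0)*d1 is not identically zero, an
    inhibiting context iff d0*(1+d1) is not.  Canonical form makes "not
    identically zero" a syntactic check.
    """
    if system.field.p != 2:
        raise ValueError("edge signs are defined for Boolean systems only")
    f = system.functions[j - 1]
    if i not in f.support:
        raise ValueError(f"edge {i}->{j} is not functional")
    d0 = f.assign({i: 0})
    d1 = f.assign({i: 1})
    one = Polynomial.constant(1, system.nvars, system.field)
    activating = not ((one + d0) * d1).is_zero
    inhibiting = not (d0 * (one + d1)).is_zero
    if activating and inhibiting:
        return None
    return 1 if activating else -1


def _canonical_cycle(nodes: list) -> tuple:
    k = nodes.index(min(nodes))
    return tuple(nodes[k:] + nodes[:k])


def elementary_circuits(wd: nx.DiGraph, cap: int = CIRCUIT_CAP) -> list:
    """All elementary circuits (including self-loops), deterministically
    ordered by length then node sequence; truncated with a warning at ``cap``.
    """
    out = []
    for cyc in nx.simple_cycles(wd):
        out.append(_canonical_cycle(list(cyc)))
        if len(out) >= cap:
            warnings.warn(
                f"circuit enumeration truncated at {cap} circuits",
                RuntimeWarning,
                stacklevel=2,
            )
            break
    out.sort(key=lambda c: (len(c), c))
    return [Circuit(c) for c in out]


def functional_circuits(system: PDS, cap: int = CIRCUIT_CAP) -> list:
    """Elementary circuits of the functional wiring diagram, with signs.

    Boolean systems only (the sign calculus needs two levels).
    """
    if system.field.p != 2:
        raise ValueError("circuit analysis is implemented for Boolean systems only")
    wd = functional_wiring_diagram(system)
    out = []
    for circ in elementary_circuits(wd, cap=cap):
        nodes = circ.nodes
        signs = tuple(
            wd.edges[nodes[k], nodes[(k + 1) % len(nodes)]]["sign"]
            for k in range(len(nodes))
        )
        out.append(Circuit(nodes, signs))
    return out


def has_positive_circuit(system: PDS, cap: int = CIRCUIT_CAP) -> bool:
    """Whether some functional circuit can realize sign +1.

    Multiple fixed points require such a circuit; non-unate edges count as
    either sign, since each sign is witnessed in some context.
    """
    return any(c.can_be_positive for c in functional_circuits(system, cap=cap))
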