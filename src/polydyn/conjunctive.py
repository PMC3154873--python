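"""Fast-path analysis of conjunctive (all-AND) and disjunctive (all-OR)
Boolean networks with strongly connected wiring diagrams.

For these networks the key dynamic features follow from the wiring diagram
alone: the only steady states are the all-zeros and all-ones states, and
every limit-cycle period divides the *loop number* — the gcd of the lengths
of the directed cycles — so the admissible periods are exactly its
divisors.  Disjunctive networks reduce to conjunctive ones by the 0<->1
duality (complement every variable), which preserves the wiring diagram.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from math import gcd

import networkx as nx

from .pds import PDS, Polynomial
from .solver import limit_cycles
from .structure import functional_wiring_diagram

__all__ = [
    "ConjunctiveSummary",
    "detect_class",
    "dual_system",
    "loop_number",
    "conjunctive_attractors",
]


@dataclass(frozen=True)
class ConjunctiveSummary:
    """Structure-derived dynamics of a conjunctive/disjunctive network."""

    network_class: str  # "conjunctive" | "disjunctive" | "neither"
    strongly_connected: bool
    loop_number: int | None
    steady_states: tuple
    admissible_periods: tuple | None  # divisors of the loop number
    fast_path: bool  # False when the general solver was used instead
    cycles: tuple = ()  # populated only on the general-solver fallback


def _is_and_polynomial(f: Polynomial) -> bool:
    if f.is_constant:
        return True
    if len(f.terms) != 1:
        return False
    (exps, coeff), = f.terms.items()
    return coeff == 1 and all(e <= 1 for e in exps)


def dual_system(system: PDS) -> PDS:
    """Complement all inputs and the output: g_i(x) = f_i(x+1) + 1 over F_2.

    Maps disjunctive systems to conjunctive ones and conjugates the
    dynamics by global complementation.
    """
    if system.field.p != 2:
        raise ValueError("duality is defined for Boolean systems")
    n, field = system.nvars, system.field
    ones = [
        Polynomial.variable(i, n, field) + 1 for i in range(1, n + 1)
    ]
    return PDS([f.substitute(ones) + 1 for f in system.functions], field)


def detect_class(system: PDS) -> str:
    """Classify a Boolean system: "conjunctive", "disjunctive" or "neither".

    Conjunctive: every canonical rule is a product of distinct variables
    (or constant).  Disjunctive: every rule is the OR of its inputs,
    checked via duality.
    """
    if system.field.p != 2:
        raise ValueError("conjunctive/disjunctive analysis requires p = 2")
    if all(_is_and_polynomial(f) for f in system.functions):
        return "conjunctive"
    if all(_is_and_polynomial(f) for f in dual_system(system).functions):
        return "disjunctive"
    return "neither"


def loop_number(wd: nx.DiGraph) -> int:
    """gcd of the lengths of all directed cycles of a strongly connected graph.

    Computed from BFS level differences: for any root, every edge (u,v)
    contributes |dist(u)+1-dist(v)| and the gcd over edges equals the gcd of
    all cycle lengths.  Requires at least one cycle.
    """
    if wd.number_of_nodes() == 0:
        raise ValueError("empty graph")
    if not nx.is_strongly_connected(wd):
        raise ValueError("wiring diagram is not strongly connected")
    if wd.number_of_edges() == 0:
        raise ValueError("graph has no cycle")
    root = min(wd.nodes)
    dist = nx.single_source_shortest_path_length(wd, root)
    g = 0
    for u, v in wd.edges:
        g = gcd(g, abs(dist[u] + 1 - dist[v]))
    if g == 0:
        raise ValueError("graph has no cycle")
    return g


def _divisors(k: int) -> tuple:
    return tuple(d for d in range(1, k + 1) if k % d == 0)


def conjunctive_attractors(system: PDS) -> ConjunctiveSummary:
    """Structure-only attractor summary for conjunctive/disjunctive networks.

    On a strongly connected wiring diagram the steady states are exactly the
    all-zeros and all-ones states and every limit-cycle period divides the
    loop number; both facts are returned after verifying the fixed points by
    evaluation.  If the system is not conjunctive/disjunctive or not
    strongly connected, the general algebraic solver is used instead (with a
    warning) and the summary is marked ``fast_path=False``.
    """
    cls = detect_class(system)
    wd = functional_wiring_diagram(system)
    sc = wd.number_of_nodes() > 0 and nx.is_strongly_connected(wd) and (
        wd.number_of_edges() > 0
    )
    if cls == "neither" or not sc:
        warnings.warn(
            "fast path requires a strongly connected conjunctive or "
            "disjunctive network; falling back to the general solver",
            RuntimeWarning,
            stacklevel=2,
        )
        cs = limit_cycles(system, min(system.nvars, 10))
        return ConjunctiveSummary(
            cls, sc, None, cs.steady_states, None, False, cs.cycles
        )
    ell = loop_number(wd)
    n = system.nvars
    candidates = [(0,) * n, (1,) * n]
    fixed = tuple(s for s in candidates if system.evaluate(s) == s)
    return ConjunctiveSummary(cls, True, ell, fixed, _divisors(ell), True)
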