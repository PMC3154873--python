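"""Probabilistic polynomial dynamical systems (generalizing PBNs).

Each coordinate owns a nonempty list of candidate update polynomials and a
probability distribution over them (uniform when unspecified).  Updates are
synchronous with the rule for each coordinate drawn independently, so a
state's successor distribution is the product of per-coordinate value
distributions.  Probabilities are exact ``Fraction``s end to end, so edge
weights out of a state always sum to exactly 1.

"True" steady states — fixed regardless of which rules fire — are the joint
solutions of f_{i,j}(x) = x_i over *all* rules j of *all* coordinates i,
which the sparse algebraic solver handles at scale.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from itertools import product
from typing import Sequence

import networkx as nx

from .pds import PDS, FieldSpec, Polynomial, all_states
from .solver import EXHAUSTIVE_THRESHOLD, StateSpaceTooLarge, solve_system

__all__ = ["ProbabilisticPDS", "probabilistic_transition_graph", "true_steady_states"]


@dataclass(frozen=True)
class ProbabilisticPDS:
    """Per-coordinate rule lists with exact probability distributions."""

    rules: tuple  # tuple of tuples of Polynomial
    probabilities: tuple  # tuple of tuples of Fraction, each summing to 1
    field: FieldSpec

    def __init__(
        self,
        rules: Sequence[Sequence[Polynomial]],
        field: FieldSpec,
        probabilities: Sequence[Sequence] | None = None,
    ) -> None:
        rl = tuple(tuple(r) for r in rules)
        n = len(rl)
        for i, coord in enumerate(rl):
            if not coord:
                raise ValueError(f"coordinate {i + 1} has no update rules")
            for f in coord:
                if f.nvars != n or f.field.p != field.p:
                    raise ValueError("rule over wrong ring")
        if probabilities is None:
            pr = tuple(
                tuple(Fraction(1, len(coord)) for _ in coord) for coord in rl
            )
        else:
            pr = tuple(
                tuple(Fraction(q) for q in coord) for coord in probabilities
            )
            for i, (coord, probs) in enumerate(zip(rl, pr)):
                if len(coord) != len(probs):
                    raise ValueError(f"coordinate {i + 1}: rule/probability mismatch")
                if any(q <= 0 or q > 1 for q in probs):
                    raise ValueError(
                        f"coordinate {i + 1}: probabilities must lie in (0,1]"
                    )
                if sum(probs) != 1:
                    raise ValueError(
                        f"coordinate {i + 1}: probabilities sum to {sum(probs)}, not 1"
                    )
        object.__setattr__(self, "rules", rl)
        object.__setattr__(self, "probabilities", pr)
        object.__setattr__(self, "field", field)

    @property
    def nvars(self) -> int:
        return len(self.rules)

    @property
    def is_deterministic(self) -> bool:
        return all(len(coord) == 1 for coord in self.rules)

    def as_pds(self) -> PDS:
        if not self.is_deterministic:
            raise ValueError("system has multiple rules per coordinate")
        return PDS([coord[0] for coord in self.rules], self.field)

    def successor_distribution(self, state) -> dict:
        """Map successor state -> exact probability (sums to 1)."""
        per_coord = []
        for coord, probs in zip(self.rules, self.probabilities):
            dist: dict = {}
            for f, q in zip(coord, probs):
                v = f.evaluate(state)
                dist[v] = dist.get(v, Fraction(0)) + q
            per_coord.append(sorted(dist.items()))
        out: dict = {}
        for combo in product(*per_coord):
            succ = tuple(v for v, _ in combo)
            w = Fraction(1)
            for _, q in combo:
                w *= q
            out[succ] = out.get(succ, Fraction(0)) + w
        return out


def probabilistic_transition_graph(
    pp: ProbabilisticPDS, threshold: int = EXHAUSTIVE_THRESHOLD
) -> nx.DiGraph:
    """All-transitions graph: edges state -> successor with exact weights."""
    size = pp.field.p**pp.nvars
    if size > threshold:
        raise StateSpaceTooLarge(
            f"state space has {size} states (> {threshold})"
        )
    g = nx.DiGraph()
    for s in all_states(pp.nvars, pp.field):
        for succ, w in pp.successor_distribution(s).items():
            g.add_edge(s, succ, weight=w)
    return g


def true_steady_states(pp: ProbabilisticPDS) -> list:
    """States fixed under every choice of update rules, sorted.

    x is fixed for every deterministic selection iff every individual rule
    already fixes its coordinate at x, so the union of equations
    f_{i,j} - x_i over all rules is an exact encoding and scales to large n.
    """
    n, field = pp.nvars, pp.field
    eqs = []
    for i, coord in enumerate(pp.rules, start=1):
        xi = Polynomial.variable(i, n, field)
        for f in coord:
            eqs.append(f - xi)
    return solve_system(eqs, field, n)
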