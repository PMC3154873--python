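"""Attractor solver: algebraic steady states / limit cycles vs enumeration."""

import random
from itertools import product

import pytest

from polydyn.netgen import GenSpec, random_sparse_pds
from polydyn.pds import PDS, FieldSpec, Polynomial, all_states
from polydyn.solver import (
    EquationSystem,
    StateSpaceTooLarge,
    attractors_from_phase_space,
    brute_force_attractors,
    build_phase_space,
    limit_cycles,
    periodic_states,
    solve_system,
    steady_states,
    trajectory,
)

from conftest import F2, F3, const, random_pds, x


class TestSolveSystem:
    def test_single_linear_equation(self):
        # x1 + 1 = 0 over F_2
        assert solve_system([x(1, 1) + 1]) == [(1,)]

    def test_affine_line(self):
        # x1 + x2 + 1 = 0 over F_2
        assert solve_system([x(1, 2) + x(2, 2) + 1]) == [(0, 1), (1, 0)]

    def test_inconsistent_system_over_f3(self):
        # x1*x2 = 1 and x1 + x2 = 0 has no F_3 solution
        eqs = [
            x(1, 2, F3) * x(2, 2, F3) - const(1, 2, F3),
            x(1, 2, F3) + x(2, 2, F3),
        ]
        brute = [
            s
            for s in all_states(2, F3)
            if all(e.evaluate(s) == 0 for e in eqs)
        ]
        assert brute == []
        assert solve_system(eqs) == []

    def test_free_variable_enumerated(self):
        # x1*x2 = 0 over F_2: three solutions, x2 free when x1 = 0
        assert solve_system([x(1, 2) * x(2, 2)]) == [(0, 0), (0, 1), (1, 0)]

    def test_zero_equation_keeps_everything(self):
        zero = Polynomial.zero(2, F2)
        assert solve_system(EquationSystem([zero], F2, 2)) == sorted(
            all_states(2, F2)
        )

    def test_random_systems_match_brute_force(self, rng):
        """The elimination search finds exactly the enumerated root sets."""
        for _ in range(30):
            field = rng.choice([F2, F3])
            n = rng.randint(1, 4)
            eqs = [
                random_pds(rng, n, field).functions[0]
                for _ in range(rng.randint(1, 3))
            ]
            want = [
                s
                for s in all_states(n, field)
                if all(e.evaluate(s) == 0 for e in eqs)
            ]
            assert solve_system(eqs, field, n) == want


class TestSteadyStates:
    def test_identity_all_states_fixed(self):
        assert steady_states(PDS.identity(3, F2)) == sorted(all_states(3, F2))

    def test_global_negation_has_no_fixed_point(self):
        n = 4
        sysm = PDS([x(i, n) + 1 for i in range(1, n + 1)], F2)
        assert steady_states(sysm) == []

    def test_random_sparse_networks_vs_enumeration(self, rng):
        for k in range(20):
            p = 3 if k % 4 == 0 else 2
            n = rng.randint(3, 12 if p == 2 else 7)
            sysm = random_sparse_pds(
                GenSpec(n=n, p=p, max_in_degree=3, seed=rng.randrange(2**31))
            )
            brute = [
                s for s in all_states(n, sysm.field) if sysm.evaluate(s) == s
            ]
            assert steady_states(sysm) == brute


class TestLimitCycles:
    def test_negation_two_cycle(self, negation1):
        cs = limit_cycles(negation1, 2)
        assert cs.steady_states == ()
        assert cs.cycles == ((2, ((0,), (1,))),)

    def test_rotation_attractors(self, rotation3):
        cs = limit_cycles(rotation3, 3)
        assert cs.steady_states == ((0, 0, 0), (1, 1, 1))
        assert [period for period, _ in cs.cycles] == [3, 3]
        # each reported orbit really is an orbit of f
        for period, orbit in cs.cycles:
            for a, b in zip(orbit, orbit[1:] + orbit[:1]):
                assert rotation3.evaluate(a) == b

    def test_length_one_equals_steady_states(self, rng):
        for _ in range(5):
            sysm = random_pds(rng, rng.randint(2, 4), F2)
            assert list(limit_cycles(sysm, 1).steady_states) == steady_states(sysm)

    def test_period_divisibility(self, rng):
        """Solutions of f^d = x for d | m are among solutions of f^m = x."""
        for _ in range(5):
            sysm = random_pds(rng, 3, F2)
            sols_m = set(periodic_states(sysm, 4))
            for d in (1, 2, 4):
                assert set(periodic_states(sysm, d)) <= sols_m

    def test_unrolled_solutions_match_composition(self, rng):
        """Dual routes: periodic_states (unrolled) vs solving f^d(x) = x on
        the symbolic composition."""
        for _ in range(5):
            n = rng.randint(2, 4)
            sysm = random_pds(rng, n, F2)
            d = rng.randint(2, 3)
            fd = sysm.compose(d)
            eqs = [
                f - Polynomial.variable(i + 1, n, F2)
                for i, f in enumerate(fd.functions)
            ]
            assert periodic_states(sysm, d) == solve_system(eqs, F2, n)

    def test_rejects_nonpositive_length(self, rotation3):
        with pytest.raises(ValueError):
            limit_cycles(rotation3, 0)


class TestPhaseSpace:
    def test_single_negation_graph(self, negation1):
        g = build_phase_space(negation1)
        assert set(g.edges) == {((0,), (1,)), ((1,), (0,))}

    def test_identity_self_loops(self):
        g = build_phase_space(PDS.identity(2, F2))
        assert all(u == v for u, v in g.edges)
        assert g.number_of_nodes() == 4

    def test_refusal_above_threshold(self, rotation3):
        with pytest.raises(StateSpaceTooLarge):
            build_phase_space(rotation3, threshold=4)

    def test_cross_method_agreement(self, rng):
        """Phase-space attractors equal the algebraic result."""
        for _ in range(5):
            n = rng.randint(2, 4)
            sysm = random_pds(rng, n, rng.choice([F2, F3]))
            via_graph = attractors_from_phase_space(build_phase_space(sysm))
            m = max((p for p, _ in via_graph.cycles), default=1)
            via_algebra = limit_cycles(sysm, m)
            assert via_graph.steady_states == via_algebra.steady_states
            assert via_graph.cycles == via_algebra.cycles


class TestTrajectory:
    def test_identity_trajectory_is_trivial(self):
        traj = trajectory(PDS.identity(2, F2), (1, 0))
        assert traj.transient == ()
        assert traj.attractor == ((1, 0),)
        assert traj.period == 1

    def test_negation_enters_two_cycle(self, negation1):
        traj = trajectory(negation1, (0,))
        assert traj.states == ((0,), (1,))
        assert traj.period == 2

    def test_transient_feeds_into_reported_attractor(self, rng):
        for _ in range(10):
            n = rng.randint(2, 4)
            sysm = random_pds(rng, n, F2)
            start = tuple(rng.randrange(2) for _ in range(n))
            traj = trajectory(sysm, start)
            if traj.transient:
                assert sysm.evaluate(traj.transient[-1]) == traj.attractor[0]
            cs = limit_cycles(sysm, traj.period)
            assert set(traj.attractor) <= cs.all_states
            # the orbit closes
            assert sysm.evaluate(traj.attractor[-1]) == traj.attractor[0]
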