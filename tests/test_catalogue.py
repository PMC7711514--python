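"""Closed-form catalogue solutions cross-checked against the generic engine."""

import math
from itertools import product

import numpy as np
import pytest

from entroprod import catalogue as cat
from entroprod import markov
from entroprod.catalogue import (
    LatticeRWSpec,
    TwoStateSpec,
    UnsupportedTopologyError,
    complete_graph_asymptote,
    complete_graph_point_start,
    complete_graph_rate_matrix,
    complete_graph_solution,
    cyclic_rate_matrix,
    distinguishable_sum,
    indistinguishable_dstate,
    indistinguishable_two_state,
    lattice_rw_density,
    lattice_rw_entropy,
    lattice_rw_entropy_asymptote,
    occupation_rate_matrix,
    ring_rw_solution,
    three_state_solution,
    two_state_rate_matrix,
    two_state_solution,
)
from entroprod.markov import entropy_rates, solve_master, validate_rate_matrix


def truncated_lattice_chain(r, l, n_half):
    """Engine oracle: the walk on Z restricted to +-n_half sites."""
    n = 2 * n_half + 1
    w = np.zeros((n, n))
    for i in range(n):
        if i + 1 < n:
            w[i, i + 1] = r
        if i - 1 >= 0:
            w[i, i - 1] = l
    return validate_rate_matrix(w), n_half  # centre index


class TestTwoState:
    def test_reaches_equilibrium(self):
        spec = TwoStateSpec(2.0, 1.0, 1.0)
        sol = two_state_solution(spec, 60.0)
        assert sol.si == pytest.approx(0.0, abs=1e-14)
        assert sol.se == pytest.approx(0.0, abs=1e-14)

    def test_stationary_start_never_produces(self):
        spec = TwoStateSpec(2.0, 1.0, p=1.0 / 3.0)  # p = beta/(alpha+beta)
        assert spec.r == pytest.approx(0.0, abs=1e-15)
        for t in [0.0, 0.5, 3.0]:
            sol = two_state_solution(spec, t)
            assert sol.si == pytest.approx(0.0, abs=1e-14)

    @pytest.mark.parametrize("t", [0.1, 0.3, 1.0, 4.0])
    def test_matches_engine(self, t):
        spec = TwoStateSpec(2.0, 1.0, 1.0)
        W = two_state_rate_matrix(spec)
        P = solve_master(W, [1.0, 0.0], t)[0]
        r = entropy_rates(P, W)
        sol = two_state_solution(spec, t)
        assert sol.P1 == pytest.approx(P[0], abs=1e-12)
        assert sol.si == pytest.approx(r.si, abs=1e-10)
        assert sol.se == pytest.approx(r.se, abs=1e-10)

    def test_invalid_parameters(self):
        with pytest.raises(ValueError):
            TwoStateSpec(-1.0, 1.0, 0.5)
        with pytest.raises(ValueError):
            TwoStateSpec(1.0, 1.0, 1.5)


class TestThreeState:
    def test_symmetric_cycle_equilibrates(self):
        sol = three_state_solution(1.5, 1.5, 40.0)
        assert sol.si == pytest.approx(0.0, abs=1e-12)
        assert sol.se == pytest.approx(0.0, abs=1e-15)

    def test_driven_cycle_stationary_production(self):
        sol = three_state_solution(2.0, 1.0, 50.0)
        assert sol.si == pytest.approx(math.log(2.0), rel=1e-10)
        assert sol.se == pytest.approx(-math.log(2.0), rel=1e-12)

    @pytest.mark.parametrize("t", [0.1, 0.5, 1.5])
    def test_matches_engine(self, t):
        W = cyclic_rate_matrix(3, 2.0, 1.0)
        P = solve_master(W, [1.0, 0.0, 0.0], t)[0]
        sol = three_state_solution(2.0, 1.0, t)
        assert np.allclose([sol.P1, sol.P2, sol.P3], P, atol=1e-12)
        r = entropy_rates(P, W)
        assert sol.si == pytest.approx(r.si, abs=1e-10)
        assert sol.se == pytest.approx(r.se, abs=1e-10)

    def test_flow_constant_in_time(self):
        values = {three_state_solution(2.0, 1.0, t).se for t in [0.2, 1.0, 3.0]}
        assert len({round(v, 12) for v in values}) == 1

    @pytest.mark.parametrize("M", [3, 4, 5, 8])
    def test_stationary_production_independent_of_cycle_length(self, M):
        """Driven M-state cycles all produce (alpha-beta) ln(alpha/beta)."""
        W = cyclic_rate_matrix(M, 2.0, 1.0)
        pi = markov.stationary_distribution(W)
        assert entropy_rates(pi, W).si == pytest.approx(math.log(2.0), rel=1e-10)


class TestCompleteGraph:
    def test_flow_is_identically_zero(self):
        P0 = np.array([0.5, 0.2, 0.1, 0.1, 0.05, 0.05])
        for t in [0.1, 1.0, 3.0]:
            _, _, se = complete_graph_solution(6, 1.0, P0, t)
            assert se == 0.0

    def test_equilibrium_at_long_times(self):
        P, si, _ = complete_graph_solution(6, 1.0, np.eye(6)[0], 10.0)
        assert si == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(P, 1 / 6)

    def test_point_start_form_equals_general_form(self):
        """The delta-start simplification equals the general expression."""
        for t in [0.2, 0.5, 1.0]:
            _, si_gen, _ = complete_graph_solution(6, 1.0, np.eye(6)[0], t)
            assert complete_graph_point_start(6, 1.0, t) == pytest.approx(
                si_gen, rel=1e-12
            )

    @pytest.mark.parametrize("t", [0.3, 0.8])
    def test_matches_engine(self, t):
        W = complete_graph_rate_matrix(6, 1.0)
        P = solve_master(W, np.eye(6)[0], t)[0]
        r = entropy_rates(P, W)
        _, si, se = complete_graph_solution(6, 1.0, np.eye(6)[0], t)
        assert si == pytest.approx(r.si, abs=1e-10)
        assert se == pytest.approx(r.se, abs=1e-12)

    def test_long_time_asymptote(self):
        """si / [d(d-1) alpha e^{-2 d alpha t}] -> 1."""
        d, alpha = 6, 1.0
        for t in [1.5, 2.0]:
            ratio = complete_graph_point_start(d, alpha, t) / \
                complete_graph_asymptote(d, alpha, t)
            assert ratio == pytest.approx(1.0, abs=2 * d * math.exp(-d * alpha * t))


class TestMultiParticle:
    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            distinguishable_sum([])

    def test_identical_particles_at_stationarity(self):
        spec = TwoStateSpec(2.0, 1.0)
        W = two_state_rate_matrix(spec)
        pi = markov.stationary_distribution(W)
        r = distinguishable_sum([(pi, W)] * 3)
        assert r.si == pytest.approx(0.0, abs=1e-12)

    def test_two_distinct_particles_equal_product_chain(self):
        """Sum of single-particle rates vs engine on the 4-state product."""
        specA, specB = TwoStateSpec(2.0, 1.0, 1.0), TwoStateSpec(0.5, 1.5, 0.0)
        WA, WB = two_state_rate_matrix(specA), two_state_rate_matrix(specB)
        t = 0.6
        PA = solve_master(WA, [1.0, 0.0], t)[0]
        PB = solve_master(WB, [0.0, 1.0], t)[0]
        r_sum = distinguishable_sum([(PA, WA), (PB, WB)])

        # product chain: states (a, b), transitions change one component
        wprod = np.zeros((4, 4))
        for (a, b), (a2, b2) in product(product(range(2), repeat=2), repeat=2):
            i, j2 = 2 * a + b, 2 * a2 + b2
            if a != a2 and b == b2:
                wprod[i, j2] = WA.w[a, a2]
            elif a == a2 and b != b2:
                wprod[i, j2] = WB.w[b, b2]
        Wprod = validate_rate_matrix(wprod)
        Pprod = np.array([PA[a] * PB[b] for a in range(2) for b in range(2)])
        r_prod = entropy_rates(Pprod, Wprod)
        assert r_sum.si == pytest.approx(r_prod.si, abs=1e-10)
        assert r_sum.se == pytest.approx(r_prod.se, abs=1e-10)

    def test_three_copies_triple_the_single_rate(self):
        spec = TwoStateSpec(2.0, 1.0, 1.0)
        W = two_state_rate_matrix(spec)
        P = solve_master(W, [1.0, 0.0], 0.4)[0]
        single = entropy_rates(P, W)
        triple = distinguishable_sum([(P, W)] * 3)
        assert triple.si == pytest.approx(3 * single.si, rel=1e-12)
        assert triple.se == pytest.approx(3 * single.se, rel=1e-12)


class TestIndistinguishable:
    def test_single_particle_has_no_correction(self):
        spec = TwoStateSpec(2.0, 1.0, 1.0)
        _, si, se = indistinguishable_two_state(1, spec, 0.4)
        sol = two_state_solution(spec, 0.4)
        assert si == pytest.approx(sol.si, rel=1e-12)
        assert se == pytest.approx(sol.se, rel=1e-12)

    def test_half_occupation_kills_the_correction(self):
        """P1 = 1/2 throughout for the symmetric chain started at p = 1/2."""
        spec = TwoStateSpec(1.0, 1.0, 0.5)
        for N in [2, 4]:
            _, si, se = indistinguishable_two_state(N, spec, 0.7)
            sol = two_state_solution(spec, 0.7)
            assert se == pytest.approx(N * sol.se, abs=1e-14)

    @pytest.mark.parametrize("N", [2, 3, 4])
    def test_occupation_chain_oracle(self, N):
        """si and se equal the engine on the (N+1)-state occupation chain."""
        spec = TwoStateSpec(2.0, 1.0, 1.0)
        t = 0.4
        occ, si, se = indistinguishable_two_state(N, spec, t)
        Wocc = occupation_rate_matrix(N, spec.alpha, spec.beta)
        P0 = np.zeros(N + 1)
        P0[N] = 1.0  # all particles in state 1 (binomial with p = 1)
        Pocc = solve_master(Wocc, P0, t)[0]
        assert np.allclose(occ, Pocc, atol=1e-12)
        r = entropy_rates(Pocc, Wocc)
        assert si == pytest.approx(r.si, abs=1e-9)
        assert se == pytest.approx(r.se, abs=1e-9)

    def test_production_is_N_fold(self):
        spec = TwoStateSpec(2.0, 1.0, 1.0)
        sol = two_state_solution(spec, 0.4)
        for N in [2, 3, 4]:
            _, si, _ = indistinguishable_two_state(N, spec, 0.4)
            assert si == pytest.approx(N * sol.si, rel=1e-12)

    def test_invalid_N(self):
        with pytest.raises(ValueError):
            indistinguishable_two_state(0, TwoStateSpec(1.0, 1.0), 0.1)


class TestIndistinguishableDState:
    def test_stationary_correction_vanishes(self, cyclic3_W):
        pi = markov.stationary_distribution(cyclic3_W)
        si, se = indistinguishable_dstate(3, cyclic3_W, pi)
        assert si == pytest.approx(-se, abs=1e-10)

    def test_occupation_chain_oracle(self, cyclic3_W):
        """N=2, d=3 cycle vs the engine on the 6-state occupation chain."""
        t = 0.5
        Ps = solve_master(cyclic3_W, [1.0, 0.0, 0.0], t)[0]
        si, se = indistinguishable_dstate(2, cyclic3_W, Ps)

        states = [n for n in product(range(3), repeat=3) if sum(n) == 2]
        idx = {s: i for i, s in enumerate(states)}
        wocc = np.zeros((len(states), len(states)))
        for s in states:
            for j in range(3):
                for k in range(3):
                    if j == k or s[j] == 0:
                        continue
                    m = list(s)
                    m[j] -= 1
                    m[k] += 1
                    wocc[idx[s], idx[tuple(m)]] += s[j] * cyclic3_W.w[j, k]
        Wocc = validate_rate_matrix(wocc)
        Pocc = np.array(
            [
                math.factorial(2)
                / np.prod([math.factorial(c) for c in s])
                * np.prod([Ps[j] ** s[j] for j in range(3)])
                for s in states
            ]
        )
        r = entropy_rates(Pocc, Wocc)
        assert si == pytest.approx(r.si, abs=1e-9)
        assert se == pytest.approx(r.se, abs=1e-9)

    def test_production_scales_with_N(self, random_W4):
        P = solve_master(random_W4, [0.5, 0.3, 0.1, 0.1], 0.3)[0]
        si1, _ = indistinguishable_dstate(1, random_W4, P)
        si4, _ = indistinguishable_dstate(4, random_W4, P)
        assert si4 / si1 == pytest.approx(4.0, rel=1e-12)

    def test_dimension_mismatch(self, cyclic3_W):
        with pytest.raises(ValueError):
            indistinguishable_dstate(2, cyclic3_W, [0.5, 0.5])


class TestLatticeRW:
    def test_initial_delta(self):
        spec = LatticeRWSpec(1.5, 0.5)
        assert lattice_rw_density(spec, 0.0, 0.0) == 1.0
        assert lattice_rw_density(spec, 1.0, 0.0) == 0.0

    def test_symmetric_walk_symmetric_density(self):
        spec = LatticeRWSpec(1.0, 1.0)
        for m in [1, 3, 7]:
            assert lattice_rw_density(spec, m, 2.0) == pytest.approx(
                lattice_rw_density(spec, -m, 2.0), rel=1e-14
            )

    def test_normalisation(self):
        spec = LatticeRWSpec(1.5, 0.5)
        total = sum(lattice_rw_density(spec, m, 2.0) for m in range(-80, 81))
        assert total == pytest.approx(1.0, abs=1e-10)

    def test_off_lattice_rejected(self):
        with pytest.raises(ValueError, match="lattice"):
            lattice_rw_density(LatticeRWSpec(1.0, 1.0), 0.5, 1.0)

    def test_density_matches_truncated_engine(self):
        spec = LatticeRWSpec(1.5, 0.5)
        W, c = truncated_lattice_chain(1.5, 0.5, 60)
        P0 = np.zeros(W.d)
        P0[c] = 1.0
        P = solve_master(W, P0, 2.0)[0]
        for m in range(-10, 11):
            assert lattice_rw_density(spec, m, 2.0) == pytest.approx(
                P[c + m], abs=1e-8
            )

    def test_entropy_matches_truncated_engine(self):
        spec = LatticeRWSpec(1.5, 0.5)
        si, se = lattice_rw_entropy(spec, 1.0)
        W, c = truncated_lattice_chain(1.5, 0.5, 40)
        P0 = np.zeros(W.d)
        P0[c] = 1.0
        P = solve_master(W, P0, 1.0)[0]
        r = entropy_rates(P, W)
        assert si == pytest.approx(r.si, abs=1e-8)
        assert se == pytest.approx(r.se, abs=1e-12)

    def test_symmetric_long_time_transient(self):
        """t si(t) -> 1/2 with O(t^-2) corrections for r = l."""
        spec = LatticeRWSpec(1.0, 1.0)
        si, se = lattice_rw_entropy(spec, 50.0)
        assert 50.0 * si == pytest.approx(0.5, abs=1e-3)
        assert se == 0.0

    def test_asymmetric_long_time_asymptote(self):
        spec = LatticeRWSpec(1.5, 0.5)
        for t in [30.0, 60.0]:
            si, _ = lattice_rw_entropy(spec, t)
            assert si == pytest.approx(
                lattice_rw_entropy_asymptote(spec, t), abs=5e-3 / t
            )

    def test_divergence_at_time_zero(self):
        si, _ = lattice_rw_entropy(LatticeRWSpec(1.0, 1.0), 0.0)
        assert math.isinf(si)

    def test_continuum_limit_is_gaussian(self):
        """With r+l = 2D/a^2, r-l = v/a the density approaches the
        drift-diffusion Gaussian as the spacing shrinks."""
        from entroprod.continuum import DiffusionSpec, dd_density_current

        D, v, t = 0.5, 0.4, 1.5
        dspec = DiffusionSpec(v=v, D=D)
        for a in [0.2, 0.1, 0.05]:
            r = D / a**2 + v / (2 * a)
            l = D / a**2 - v / (2 * a)
            spec = LatticeRWSpec(r, l, spacing=a)
            xs = a * np.arange(-int(3 / a), int(3 / a) + 1)
            lattice = np.array(
                [lattice_rw_density(spec, x, t) / a for x in xs]
            )
            gauss = dd_density_current(dspec, xs, t)[0]
            err = np.max(np.abs(lattice - gauss))
            assert err < 0.5 * a  # first-order convergence in the spacing


class TestRingRW:
    def test_two_site_ring_refused(self):
        with pytest.raises(UnsupportedTopologyError):
            LatticeRWSpec(1.0, 1.0, circumference=2.0)

    def test_symmetric_ring_equilibrates(self):
        spec = LatticeRWSpec(1.0, 1.0, circumference=5.0)
        _, si, se = ring_rw_solution(spec, 50.0)
        assert si == pytest.approx(0.0, abs=1e-12)
        assert se == 0.0

    def test_driven_ring_stationary_production(self):
        spec = LatticeRWSpec(2.0, 1.0, circumference=5.0)
        _, si, se = ring_rw_solution(spec, 40.0)
        assert si == pytest.approx(math.log(2.0), rel=1e-10)
        assert se == pytest.approx(-math.log(2.0), rel=1e-12)

    @pytest.mark.parametrize("t", [0.3, 0.7, 2.0])
    def test_matches_cyclic_engine(self, t):
        spec = LatticeRWSpec(2.0, 1.0, circumference=5.0)
        P, si, se = ring_rw_solution(spec, t)
        W = cyclic_rate_matrix(5, 2.0, 1.0)
        P0 = np.zeros(5)
        P0[0] = 1.0
        Pe = solve_master(W, P0, t)[0]
        assert np.allclose(P, Pe, atol=1e-12)
        r = entropy_rates(Pe, W)
        assert si == pytest.approx(r.si, abs=1e-9)
        assert se == pytest.approx(r.se, abs=1e-12)

    def test_total_rate_vanishes_at_long_times(self):
        spec = LatticeRWSpec(2.0, 1.0, circumference=5.0)
        _, si, se = ring_rw_solution(spec, 30.0)
        assert si + se == pytest.approx(0.0, abs=1e-10)
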