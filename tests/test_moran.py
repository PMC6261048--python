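"""Transition kernel, cleared polynomial system, solvers, orbit reduction."""

import random
from fractions import Fraction

import pytest

import graphfix as gf
from graphfix.moran import MutantConfiguration, build_polynomial_system


class TestMutantConfiguration:
    def test_encoding_roundtrip(self):
        c = MutantConfiguration.from_vertices([1, 3], order=4)
        assert c.encoding == 0b101
        assert c.vertices == (1, 3)
        assert c.size == 2
        assert not c.is_absorbing

    def test_absorbing_states(self):
        assert MutantConfiguration(0, 4).is_absorbing
        assert MutantConfiguration(15, 4).is_absorbing

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            MutantConfiguration(16, 4)


class TestWeightMatrix:
    def test_rows_sum_to_one(self, small_graph_zoo):
        for g in small_graph_zoo:
            W = gf.weight_matrix(g)
            for row in W:
                assert sum(row, Fraction(0)) == 1

    def test_positive_exactly_on_edges(self):
        g = gf.star(4)
        W = gf.weight_matrix(g)
        for i in range(4):
            for j in range(4):
                expected = (i + 1, j + 1) in g.edges or (j + 1, i + 1) in g.edges
                assert (W[i][j] > 0) == expected


class TestTransitionRow:
    def test_k2_single_mutant(self):
        g = gf.clique(2)
        row = gf.transition_row(g, 0b01, Fraction(3, 2))
        r = Fraction(3, 2)
        assert row[0b11] == r / (r + 1)
        assert row[0b00] == 1 / (r + 1)
        assert 0b01 not in row  # no self-loop on K2

    def test_star3_centre_mutant_at_r2(self):
        # centre weight 1/2 per leaf, w_S = 4, leaves non-adjacent
        g = gf.star(3)
        row = gf.transition_row(g, 0b001, 2)
        assert row[0b011] == Fraction(1, 4)
        assert row[0b101] == Fraction(1, 4)
        assert row[0b000] == Fraction(1, 2)
        assert row.get(0b001, 0) == 0

    def test_rejects_non_positive_fitness(self):
        with pytest.raises(ValueError, match="positive"):
            gf.transition_row(gf.clique(2), 1, 0)

    def test_row_stochasticity_random_triples(self, small_graph_zoo):
        rng = random.Random(99)
        for g in small_graph_zoo:
            for _ in range(20):
                s = rng.randrange(1, (1 << g.order) - 1)
                r = Fraction(rng.randrange(1, 40), rng.randrange(1, 12))
                row = gf.transition_row(g, s, r)
                assert sum(row.values(), Fraction(0)) == 1


class TestPolynomialSystem:
    def test_k2_lumps_to_the_one_state_system(self):
        # both vertices are symmetric: a single orbit state with (r+1) Phi = r
        sys_ = build_polynomial_system(gf.clique(2), lumped=True)
        assert sys_.n == 1
        assert sys_.q_star(0, 0) == (Fraction(1), Fraction(1))
        assert sys_.c_star(0) == (Fraction(0), Fraction(1))
        assert sys_.b_star(0) == (Fraction(1), Fraction(0))

    def test_cleared_rows_total_w_S(self, small_graph_zoo):
        """Cleared transition terms plus both absorption columns give
        w_S(r) = r|S| + N - |S| exactly, the cleared image of
        row-stochasticity.  Q* = w_S I - (cleared transitions), so the
        transition term at (k, l) is delta_{kl} w_S - q*(k, l)."""
        for g in small_graph_zoo[:6]:
            sys_ = build_polynomial_system(g)
            N = g.order
            for k, s in enumerate(sys_.states):
                size = bin(s).count("1")
                wS = (Fraction(N - size), Fraction(size))
                const = sum((-sys_.q_star(k, l)[0] for l in range(sys_.n)),
                            wS[0] + sys_.c_star(k)[0] + sys_.b_star(k)[0])
                rcoef = sum((-sys_.q_star(k, l)[1] for l in range(sys_.n)),
                            wS[1] + sys_.c_star(k)[1] + sys_.b_star(k)[1])
                assert (const, rcoef) == wS

    def test_state_count(self):
        sys_ = build_polynomial_system(gf.cycle(4))
        assert sys_.n == 2 ** 4 - 2


class TestSolveFixation:
    def test_k2_closed_form(self):
        for r in (Fraction(1, 2), 1, 2, Fraction(7, 3)):
            fv = gf.solve_fixation(gf.clique(2), r, mode="exact")
            assert fv.average == Fraction(r) / (Fraction(r) + 1)

    def test_cycle_matches_homogeneous_baseline(self):
        # isothermal: average equals Phi0(2) = (2^N - 2^{N-1}) / (2^N - 1)
        for N in (3, 4, 5, 6):
            fv = gf.solve_fixation(gf.cycle(N), 2, mode="exact")
            assert fv.average == Fraction(2 ** N - 2 ** (N - 1), 2 ** N - 1)

    def test_star3_matches_brute_force(self, oracle):
        fv = gf.solve_fixation(gf.star(3), 2, mode="exact")
        psi = oracle(gf.star(3), 2)
        for s, val in fv.psi.items():
            assert val == psi[s]

    def test_neutral_average_is_one_over_N(self, small_graph_zoo):
        for g in small_graph_zoo:
            fv = gf.solve_fixation(g, 1, mode="exact")
            assert fv.average == Fraction(1, g.order)

    def test_probabilities_strictly_inside_unit_interval(self):
        fv = gf.solve_fixation(gf.ell_graph(6, 2, 2), Fraction(3, 2),
                               mode="exact")
        assert all(0 < v < 1 for v in fv.psi.values())

    def test_float_mode_matches_exact(self, small_graph_zoo):
        for g in small_graph_zoo:
            for r in (0.25, 2.0, 10.0):
                ex = gf.solve_fixation(g, Fraction(r).limit_denominator(10**6),
                                       mode="exact").average
                fl = gf.solve_fixation(g, r, mode="float").average
                assert abs(fl - float(ex)) <= 1e-10 * float(ex)

    def test_highprec_mode(self):
        import mpmath
        fv = gf.solve_fixation(gf.star(4), 2, mode="highprec", digits=60)
        ex = gf.solve_fixation(gf.star(4), 2, mode="exact").average
        assert abs(fv.average - mpmath.mpf(ex.numerator) / ex.denominator) \
            < mpmath.mpf(10) ** -40

    def test_grid_solver_matches_pointwise(self):
        g = gf.ell_graph(6, 2, 2)
        rs = [0.5, 1.0, 2.0, 5.0, 10.0]
        grid = gf.solve_fixation_grid(g, rs)
        for r, v in zip(rs, grid):
            assert abs(v - gf.solve_fixation(g, r, mode="float").average) < 1e-12

    def test_exact_mode_requires_rational_r(self):
        with pytest.raises(TypeError):
            gf.solve_fixation(gf.clique(2), 1.5, mode="exact")

    def test_non_positive_fitness_rejected(self):
        with pytest.raises(ValueError):
            gf.solve_fixation(gf.clique(2), 0)

    def test_fixation_vector_boundary_conventions(self):
        fv = gf.solve_fixation(gf.clique(3), 2, mode="exact")
        assert fv[0] == 0 and fv[(1 << 3) - 1] == 1


class TestOrbitReduction:
    def test_star_orbit_count(self):
        # (centre in S?, number of leaves in S) pairs -> 2N - 2 non-absorbing
        for N in (3, 4, 5, 6):
            red = gf.orbit_reduce(gf.star(N))
            assert red.reduced_system.n == 2 * N - 2

    def test_cycle_orbit_count_is_necklaces(self):
        # binary necklaces of length N under the dihedral group, minus 2
        def necklaces(N):
            seen = set()
            for mask in range(1 << N):
                best = min(
                    min(((mask >> k) | (mask << (N - k))) & ((1 << N) - 1)
                        for k in range(N)),
                    min(((rev >> k) | (rev << (N - k))) & ((1 << N) - 1)
                        for k in range(N)
                        for rev in [int(format(mask, f"0{N}b")[::-1], 2)]))
                seen.add(best)
            return len(seen)

        for N in (4, 5, 6):
            red = gf.orbit_reduce(gf.cycle(N))
            assert red.reduced_system.n == necklaces(N) - 2

    def test_clique_reduces_to_birth_death_chain(self):
        red = gf.orbit_reduce(gf.clique(5))
        assert red.reduced_system.n == 4
        fv = gf.solve_fixation(gf.clique(5), 2, mode="exact", lumped=True)
        assert fv.average == Fraction(2 ** 5 - 2 ** 4, 2 ** 5 - 1)

    def test_lumpability_of_transition_weights(self):
        """Any two states in an orbit send identical total weight into every
        other orbit, as exact polynomials (checked at two fitness values)."""
        g = gf.ell_graph(6, 2, 2)
        red = gf.orbit_reduce(g)
        orbit = red.orbit_of
        by_orbit = {}
        for s in range(1, (1 << g.order) - 1):
            by_orbit.setdefault(int(orbit[s]), []).append(s)
        rng = random.Random(3)
        mates = [v for v in by_orbit.values() if len(v) > 1]
        for members in rng.sample(mates, 5):
            s1, s2 = members[0], members[1]
            for r in (Fraction(2), Fraction(1, 3)):
                rows = [gf.transition_row(g, s, r) for s in (s1, s2)]
                sums = []
                for row in rows:
                    agg = {}
                    for t, p in row.items():
                        agg[int(orbit[t])] = agg.get(int(orbit[t]), Fraction(0)) + p
                    sums.append(agg)
                assert sums[0] == sums[1]

    def test_full_and_reduced_solves_agree(self, small_graph_zoo):
        for g in [gf.star(5), gf.cycle(6), gf.ell_graph(6, 2, 2),
                  gf.complete_bipartite(2, 3)]:
            full = gf.solve_fixation(g, Fraction(5, 2), mode="exact")
            red = gf.solve_fixation(g, Fraction(5, 2), mode="exact", lumped=True)
            assert full.psi == red.psi
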