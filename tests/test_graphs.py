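"""Graph construction, families, temperatures, canonical ids, enumeration."""

import random
from fractions import Fraction

import pytest
from hypothesis import given, settings, strategies as st

import graphfix as gf
from graphfix import UndirectedGraph
from graphfix.graph import GraphParameterError


class TestConstruction:
    def test_rejects_self_loop(self):
        with pytest.raises(ValueError, match="simple"):
            UndirectedGraph([(1, 1), (1, 2)])

    def test_rejects_duplicate_edge(self):
        with pytest.raises(ValueError, match="simple"):
            UndirectedGraph([(1, 2), (2, 1)])

    def test_rejects_disconnected(self):
        with pytest.raises(ValueError, match="connected"):
            UndirectedGraph([(1, 2), (3, 4)])

    def test_rejects_trivial_order(self):
        with pytest.raises(ValueError, match="order"):
            UndirectedGraph([], order=1)

    def test_edges_normalised_unordered(self):
        g = UndirectedGraph([(2, 1), (3, 1)])
        assert g.edges == frozenset({(1, 2), (1, 3)})
        assert g.degrees == (2, 1, 1)


class TestFamilies:
    def test_ell6_matches_clique_plus_two_construction(self):
        # K4 plus u,v with edge {u,v}, u~{1,2}, v~{3,4}: 11 edges
        g = gf.ell_graph(6, 2, 2)
        assert g.size == 11
        explicit = UndirectedGraph(
            [(i, j) for i in range(1, 5) for j in range(i + 1, 5)]
            + [(5, 6), (5, 1), (5, 2), (6, 3), (6, 4)])
        assert g.isomorphic(explicit)

    def test_friendship_cycle_7_2(self):
        g = gf.friendship_cycle(7, 2)
        assert g.size == 10
        assert g.degrees[6] == 4  # centre joined to two disjoint pairs

    def test_star_on_three_vertices(self):
        g = gf.make_family(gf.FamilySpec("star", 3))
        assert g.edges == frozenset({(1, 2), (1, 3)})

    def test_ell_parameter_validation(self):
        with pytest.raises(GraphParameterError, match="n \\+ m"):
            gf.ell_graph(6, 3, 2)
        with pytest.raises(GraphParameterError):
            gf.ell_graph(4, 1, 1)

    def test_friendship_cycle_parameter_validation(self):
        with pytest.raises(GraphParameterError):
            gf.friendship_cycle(7, 4)  # 2m > N - 1

    def test_friendship_star_counts(self):
        g = gf.friendship_star(10, 6)
        assert g.order == 10
        # 6 triangles, centre in 6 of them... count triangles explicitly
        tri = sum(1 for a in range(1, 11) for b in range(a + 1, 11)
                  for c in range(b + 1, 11)
                  if {(a, b), (b, c), (a, c)} <= g.edges)
        assert tri == 6

    def test_friendship_ribbon_no_vertex_in_three_triangles(self):
        g = gf.friendship_ribbon(10, 6)
        assert g.order == 10
        per_vertex = {v: 0 for v in range(1, 11)}
        tri = 0
        for a in range(1, 11):
            for b in range(a + 1, 11):
                for c in range(b + 1, 11):
                    if {(a, b), (b, c), (a, c)} <= g.edges:
                        tri += 1
                        for v in (a, b, c):
                            per_vertex[v] += 1
        assert tri == 6
        assert max(per_vertex.values()) <= 2

    def test_unknown_family_rejected(self):
        with pytest.raises(GraphParameterError, match="unknown family"):
            gf.FamilySpec("moebius", 6)


class TestTemperatures:
    def test_star_temperatures(self):
        for N in (3, 5, 8):
            g = gf.star(N)
            t = g.temperatures
            assert t[0] == N - 1
            assert all(x == Fraction(1, N - 1) for x in t[1:])

    @pytest.mark.parametrize("g", [gf.cycle(5), gf.clique(6),
                                   gf.complete_bipartite(3, 3)])
    def test_regular_graph_temperatures_all_one(self, g):
        assert set(g.temperatures) == {Fraction(1)}

    def test_ell_extra_vertex_temperatures(self):
        # ell6: u has degree 3 with neighbours v (deg 3) and two K4 vertices,
        # each of degree 4 (three clique edges plus one extra-vertex edge)
        t6 = gf.ell_graph(6, 2, 2).temperatures
        assert t6[4] == Fraction(1, 3) + 2 * Fraction(1, 4)
        # ell7: the clique is K5, so u's two clique neighbours have degree 5
        t7 = gf.ell_graph(7, 2, 2).temperatures
        assert t7[5] == Fraction(1, 3) + 2 * Fraction(1, 5)

    def test_temperature_sum_equals_order(self, small_graph_zoo):
        for g in small_graph_zoo:
            assert sum(g.temperatures, Fraction(0)) == g.order


class TestIsothermal:
    def test_cycles_isothermal(self):
        assert gf.is_isothermal(gf.cycle(7))

    def test_star_not_isothermal(self):
        assert not gf.is_isothermal(gf.star(4))

    def test_two_four_regular_graphs_of_order_seven(self):
        regs = [g for g in gf.enumerate_connected(7)
                if set(g.degrees) == {4}]
        assert len(regs) == 2
        assert all(g.is_isothermal for g in regs)


class TestCanonicalId:
    def test_k2_and_k3_ids(self):
        assert gf.clique(2).canonical_id == 3
        assert gf.clique(3).canonical_id == 2 ** 3 + 7

    def test_path3_has_two_pair_bits(self):
        gid = UndirectedGraph([(1, 2), (2, 3)]).canonical_id
        assert gid >> 3 == 1  # sentinel at C(3,2)
        assert bin(gid & 0b111).count("1") == 2

    def test_decode_roundtrip(self, small_graph_zoo):
        for g in small_graph_zoo:
            back = gf.decode_canonical_id(g.canonical_id)
            assert back.canonical_id == g.canonical_id
            assert g.isomorphic(back)

    def test_isomorphism_invariance_under_relabelling(self, small_graph_zoo):
        rng = random.Random(7)
        for g in small_graph_zoo:
            base = g.canonical_id
            verts = list(range(1, g.order + 1))
            for _ in range(10):
                perm = verts[:]
                rng.shuffle(perm)
                relab = UndirectedGraph(
                    [(perm[i - 1], perm[j - 1]) for i, j in g.edges],
                    order=g.order)
                assert relab.canonical_id == base

    def test_large_order_rejected(self):
        g = gf.cycle(11)
        with pytest.raises(ValueError, match="64-bit"):
            _ = g.canonical_id


class TestSerialization:
    def test_graph6_roundtrip(self, small_graph_zoo):
        for g in small_graph_zoo:
            back = UndirectedGraph.from_graph6(g.to_graph6())
            assert back.canonical_id == g.canonical_id

    def test_edgelist_roundtrip_preserves_labels(self):
        g = gf.ell_graph(7, 2, 3)
        back = UndirectedGraph.from_edgelist(g.to_edgelist())
        assert back.edges == g.edges and back.order == g.order

    def test_edgelist_ignores_comments_and_blanks(self):
        text = "# a comment\n\n1 2\n 2 3 \n"
        g = UndirectedGraph.from_edgelist(text)
        assert g.edges == frozenset({(1, 2), (2, 3)})


class TestEnumeration:
    @pytest.mark.parametrize("N,count", [(2, 1), (3, 2), (4, 6), (5, 21),
                                         (6, 112), (7, 853)])
    def test_connected_class_counts(self, N, count):
        graphs = list(gf.enumerate_connected(N))
        assert len(graphs) == count
        ids = [g.canonical_id for g in graphs]
        assert len(set(ids)) == count and ids == sorted(ids)

    def test_matches_brute_force_dedup_for_small_orders(self):
        # filter all labelled graphs, keep connected, dedupe by canonical id
        for N in (3, 4, 5):
            pairs = [(i, j) for i in range(1, N + 1) for j in range(i + 1, N + 1)]
            seen = set()
            for mask in range(1, 1 << len(pairs)):
                edges = [pairs[k] for k in range(len(pairs)) if (mask >> k) & 1]
                try:
                    g = UndirectedGraph(edges, order=N)
                except ValueError:
                    continue
                seen.add(g.canonical_id)
            assert len(seen) == len(list(gf.enumerate_connected(N)))

    def test_out_of_range_orders_rejected(self):
        with pytest.raises(ValueError):
            list(gf.enumerate_connected(1))
        with pytest.raises(ValueError):
            list(gf.enumerate_connected(9))


class TestCounting:
    @pytest.mark.parametrize("N,count", [(2, 1), (3, 2), (4, 6), (5, 21),
                                         (6, 112), (7, 853), (8, 11117),
                                         (9, 261080), (10, 11716571)])
    def test_connected_unlabeled_counts(self, N, count):
        assert gf.count_connected_unlabeled(N) == count

    def test_total_up_to_order_ten(self):
        assert sum(gf.count_connected_unlabeled(n)
                   for n in range(2, 11)) == 11_989_763

    def test_counting_agrees_with_enumeration(self):
        for N in range(2, 8):
            assert gf.count_connected_unlabeled(N) == len(
                list(gf.enumerate_connected(N)))


@settings(deadline=None, max_examples=25, derandomize=True)
@given(st.integers(min_value=3, max_value=7), st.data())
def test_random_graph_invariants(N, data):
    """Temperatures sum to N and ids are label-invariant on random graphs."""
    pairs = [(i, j) for i in range(1, N + 1) for j in range(i + 1, N + 1)]
    mask = data.draw(st.integers(min_value=1, max_value=(1 << len(pairs)) - 1))
    edges = [pairs[k] for k in range(len(pairs)) if (mask >> k) & 1]
    try:
        g = UndirectedGraph(edges, order=N)
    except ValueError:
        return
    assert sum(g.temperatures, Fraction(0)) == N
    perm = data.draw(st.permutations(list(range(1, N + 1))))
    relab = UndirectedGraph([(perm[i - 1], perm[j - 1]) for i, j in g.edges],
                            order=N)
    assert relab.canonical_id == g.canonical_id
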