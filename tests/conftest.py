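"""Shared fixtures and the independent brute-force fixation oracle.

The oracle builds the raw stochastic system (I - Q(r)) Psi = c(r) directly
from the model definition with Fraction arithmetic and solves it by plain
Gaussian elimination.  It shares no code with the package's cleared-system
assembly, orbit lumping, modular resolvent or interpolation routes, so
agreement between the two is a genuine cross-check.
"""

from fractions import Fraction

import pytest

from graphfix import UndirectedGraph


def brute_force_fixation(G: UndirectedGraph, r) -> dict:
    """Fixation probability for every state, straight from the definition."""
    r = Fraction(r)
    N = G.order
    deg = G.degrees
    adj = G.adjacency
    full = (1 << N) - 1
    states = [s for s in range(1, full)]
    idx = {s: k for k, s in enumerate(states)}
    n = len(states)

    def w(i, j):  # 1-based, replacement weight i -> j
        return Fraction(1, deg[i - 1]) if j in adj[i] else Fraction(0)

    # rows of I - Q, rhs c
    M = [[Fraction(0)] * n for _ in range(n)]
    rhs = [Fraction(0)] * n
    for s in states:
        k = idx[s]
        size = bin(s).count("1")
        wS = r * size + (N - size)
        M[k][k] += 1
        for j in range(1, N + 1):
            jb = 1 << (j - 1)
            if s & jb:
                p = sum(w(i, j) for i in range(1, N + 1)
                        if not (s >> (i - 1)) & 1) / wS
                t = s ^ jb
                if t != 0:
                    M[k][idx[t]] -= p
            else:
                p = r * sum(w(i, j) for i in range(1, N + 1)
                            if (s >> (i - 1)) & 1) / wS
                t = s | jb
                if t == full:
                    rhs[k] += p
                else:
                    M[k][idx[t]] -= p
        stay = (r * sum(w(i, j) for i in range(1, N + 1) for j in range(1, N + 1)
                        if (s >> (i - 1)) & 1 and (s >> (j - 1)) & 1)
                + sum(w(i, j) for i in range(1, N + 1) for j in range(1, N + 1)
                      if not (s >> (i - 1)) & 1 and not (s >> (j - 1)) & 1)) / wS
        M[k][k] -= stay
    # plain Gaussian elimination
    for col in range(n):
        piv = next(row for row in range(col, n) if M[row][col] != 0)
        M[col], M[piv] = M[piv], M[col]
        rhs[col], rhs[piv] = rhs[piv], rhs[col]
        inv = 1 / M[col][col]
        M[col] = [x * inv for x in M[col]]
        rhs[col] *= inv
        for row in range(n):
            if row != col and M[row][col] != 0:
                f = M[row][col]
                M[row] = [a - f * b for a, b in zip(M[row], M[col])]
                rhs[row] -= f * rhs[col]
    out = {s: rhs[idx[s]] for s in states}
    out[0] = Fraction(0)
    out[full] = Fraction(1)
    return out


def brute_force_average(G: UndirectedGraph, r) -> Fraction:
    psi = brute_force_fixation(G, r)
    return sum(psi[1 << v] for v in range(G.order)) / G.order


@pytest.fixture(scope="session")
def oracle():
    return brute_force_fixation


@pytest.fixture(scope="session")
def oracle_average():
    return brute_force_average


@pytest.fixture(scope="session")
def small_graph_zoo():
    """A seeded assortment of named and random connected graphs, orders 3-6."""
    import random
    import graphfix as gf

    rng = random.Random(20240917)
    zoo = [gf.clique(3), gf.cycle(4), gf.star(4), gf.clique(4),
           gf.cycle(5), gf.star(5), gf.complete_bipartite(2, 3),
           gf.ell_graph(6, 2, 2), gf.cycle(6), gf.star(6)]
    # random connected graphs on 5 and 6 vertices
    for N in (5, 6):
        made = 0
        while made < 5:
            edges = [(i, j) for i in range(1, N + 1) for j in range(i + 1, N + 1)
                     if rng.random() < 0.5]
            try:
                zoo.append(UndirectedGraph(edges, order=N))
                made += 1
            except ValueError:
                continue
    return zoo
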