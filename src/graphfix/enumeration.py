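"""Exhaustive enumeration and counting of small connected graphs.

Enumeration proceeds order by order: every connected graph on N vertices
arises from a connected graph on N - 1 vertices by attaching a new vertex to
a non-empty neighbourhood (delete a non-cut vertex of a spanning-tree leaf to
see this), so augmenting all order-(N-1) representatives and deduplicating by
canonical form yields exactly one representative per isomorphism class.

Counting uses the cycle index of the pair action of the symmetric group
(orbit counting over vertex permutations) followed by the Euler/Riddell
transform that extracts connected counts from total unlabelled counts.  This
gives the per-order class counts for all orders up to 10 in milliseconds and
cross-checks the enumerator where both apply.
"""

from __future__ import annotations

from fractions import Fraction
from functools import lru_cache
from math import factorial, gcd
from typing import Iterator

from .graph import UndirectedGraph

__all__ = [
    "enumerate_connected",
    "count_connected_unlabeled",
    "count_unlabeled",
]

MAX_ENUM_ORDER = 8


def _canon_key(edges: list[tuple[int, int]], n: int):
    import igraph
    g = igraph.Graph(n, [(i - 1, j - 1) for i, j in edges])
    perm = g.canonical_permutation()
    g2 = g.permute_vertices(perm)
    return tuple(sorted(tuple(sorted((e.source + 1, e.target + 1))) for e in g2.es))


@lru_cache(maxsize=None)
def _connected_edge_sets(N: int) -> tuple[tuple[tuple[int, int], ...], ...]:
    if N == 2:
        return (((1, 2),),)
    reps: dict = {}
    for g in _connected_edge_sets(N - 1):
        for sub in range(1, 1 << (N - 1)):
            edges = list(g) + [(i + 1, N) for i in range(N - 1) if (sub >> i) & 1]
            key = _canon_key(edges, N)
            if key not in reps:
                reps[key] = key
    return tuple(sorted(reps.values()))


def enumerate_connected(N: int) -> Iterator[UndirectedGraph]:
    """Yield one representative per isomorphism class of connected simple
    graphs on ``N`` vertices, in ascending canonical-id order.

    Supported for 2 <= N <= 8 with the built-in generator; larger orders can
    be ingested from external graph6 lists instead.
    """
    if not 2 <= N <= MAX_ENUM_ORDER:
        raise ValueError(
            f"built-in enumeration supports 2 <= N <= {MAX_ENUM_ORDER}; "
            "ingest an external graph6 list for larger orders")
    graphs = [UndirectedGraph(edges, order=N) for edges in _connected_edge_sets(N)]
    graphs.sort(key=lambda g: g.canonical_id)
    yield from graphs


# -- cycle-index counting ----------------------------------------------------

def _partitions(n: int, maxpart: int | None = None) -> Iterator[tuple[int, ...]]:
    if n == 0:
        yield ()
        return
    if maxpart is None or maxpart > n:
        maxpart = n
    for k in range(maxpart, 0, -1):
        for rest in _partitions(n - k, k):
            yield (k,) + rest


def _perm_count(n: int, part: tuple[int, ...]) -> int:
    """Number of permutations of S_n with cycle type ``part``."""
    counts: dict[int, int] = {}
    for k in part:
        counts[k] = counts.get(k, 0) + 1
    denom = 1
    for k, c in counts.items():
        denom *= (k ** c) * factorial(c)
    return factorial(n) // denom


def _pair_orbits(part: tuple[int, ...]) -> int:
    """Number of orbits of the induced action on unordered vertex pairs."""
    total = 0
    # pairs within one cycle of length k: floor(k/2) orbits
    for k in part:
        total += k // 2
    # pairs across two distinct cycles of lengths k, l: gcd(k, l) orbits
    for a in range(len(part)):
        for b in range(a + 1, len(part)):
            total += gcd(part[a], part[b])
    return total


@lru_cache(maxsize=None)
def count_unlabeled(N: int) -> int:
    """Number of isomorphism classes of simple graphs on ``N`` vertices
    (connected or not), by Burnside orbit counting over S_N."""
    if N < 1:
        raise ValueError("N >= 1 required")
    acc = 0
    for part in _partitions(N):
        acc += _perm_count(N, part) * (1 << _pair_orbits(part))
    assert acc % factorial(N) == 0
    return acc // factorial(N)


@lru_cache(maxsize=None)
def count_connected_unlabeled(N: int) -> int:
    """Number of isomorphism classes of *connected* simple graphs on ``N``
    vertices, via the inverse Euler transform of the unlabelled counts."""
    if N < 1:
        raise ValueError("N >= 1 required")
    # a_n: all unlabelled graphs; generating identity
    #   1 + sum a_n x^n = prod_n (1 - x^n)^(-c_n)
    # log gives  m * l_m = sum_{d | m} d * c_d  with l_m from the formal log.
    a = [1] + [count_unlabeled(n) for n in range(1, N + 1)]
    # formal log of A(x) up to degree N
    logs = [Fraction(0)] * (N + 1)
    # l = log(1 + u) with u = A - 1: l = sum (-1)^{k+1} u^k / k
    u = [Fraction(x) for x in a]
    u[0] = Fraction(0)
    term = u[:]  # u^k, starting k = 1
    sign = 1
    for k in range(1, N + 1):
        for m in range(N + 1):
            logs[m] += Fraction(sign, k) * term[m]
        # next power u^{k+1}
        nxt = [Fraction(0)] * (N + 1)
        for i in range(N + 1):
            if term[i] == 0:
                continue
            for j in range(1, N + 1 - i):
                nxt[i + j] += term[i] * u[j]
        term = nxt
        sign = -sign
    c: dict[int, int] = {}
    for m in range(1, N + 1):
        s = m * logs[m]
        for d in range(1, m):
            if m % d == 0:
                s -= d * c[d]
        cd = s / m
        assert cd.denominator == 1
        c[m] = int(cd)
    return c[N]
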