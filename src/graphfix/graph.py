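"""Undirected graphs for evolutionary dynamics: construction, families, identification.

Vertices are labelled 1..N at the API surface.  A graph must be simple and
connected: the Moran process started from a single mutant can only fix on a
connected graph, and multi-edges/self-loops have no meaning in the model.

The *temperature* of a vertex is ``T_i = sum_{j ~ i} 1/d_j``; a graph is
*isothermal* when every vertex has the same temperature, which for undirected
graphs is equivalent to regularity.  Isothermal graphs have the same fixation
probability as the homogeneous (complete-graph) population.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from functools import cached_property
from math import comb
from typing import Iterable

import igraph as _ig
import networkx as _nx

__all__ = [
    "UndirectedGraph",
    "FamilySpec",
    "make_family",
    "clique",
    "cycle",
    "star",
    "complete_bipartite",
    "ell_graph",
    "friendship_cycle",
    "friendship_star",
    "friendship_ribbon",
    "temperatures",
    "is_isothermal",
    "canonical_id",
    "decode_canonical_id",
    "MAX_ID_ORDER",
]

#: Largest order for which the sentinel-bit id fits into 64 bits
#: (1 + C(11,2) = 56 bits at N = 11; C(12,2) = 66 would overflow).
MAX_ID_ORDER = 10


class GraphParameterError(ValueError):
    """A graph-family parameter violates its constraint."""


@dataclass(frozen=True)
class UndirectedGraph:
    """A simple connected undirected graph on vertices ``1..order``.

    Parameters
    ----------
    order:
        Number of vertices, at least 2.
    edges:
        Unordered vertex pairs with 1-based labels.
    """

    order: int
    edges: frozenset[tuple[int, int]]
    name: str = field(default="", compare=False)

    def __init__(self, edges: Iterable[tuple[int, int]], order: int | None = None,
                 name: str = ""):
        norm = set()
        seen_max = 0
        for i, j in edges:
            i, j = int(i), int(j)
            if i == j:
                raise ValueError(f"self-loop at vertex {i}: graph must be simple")
            if i > j:
                i, j = j, i
            if (i, j) in norm:
                raise ValueError(f"duplicate edge {{{i},{j}}}: graph must be simple")
            if i < 1:
                raise ValueError("vertex labels are 1-based")
            norm.add((i, j))
            seen_max = max(seen_max, j)
        if order is None:
            order = seen_max
        if order < 2:
            raise ValueError("order must be at least 2")
        if seen_max > order:
            raise ValueError(f"edge mentions vertex {seen_max} > order {order}")
        object.__setattr__(self, "order", order)
        object.__setattr__(self, "edges", frozenset(norm))
        object.__setattr__(self, "name", name)
        if not self._connected():
            raise ValueError("graph must be connected")

    # -- basic structure ---------------------------------------------------

    def _connected(self) -> bool:
        adj = self.adjacency
        seen = {1}
        stack = [1]
        while stack:
            v = stack.pop()
            for w in adj[v]:
                if w not in seen:
                    seen.add(w)
                    stack.append(w)
        return len(seen) == self.order

    @cached_property
    def adjacency(self) -> dict[int, tuple[int, ...]]:
        """Sorted neighbour lists keyed by 1-based vertex."""
        adj: dict[int, list[int]] = {v: [] for v in range(1, self.order + 1)}
        for i, j in self.edges:
            adj[i].append(j)
            adj[j].append(i)
        return {v: tuple(sorted(ws)) for v, ws in adj.items()}

    @cached_property
    def degrees(self) -> tuple[int, ...]:
        """Vertex degrees, index 0 holding the degree of vertex 1."""
        return tuple(len(self.adjacency[v]) for v in range(1, self.order + 1))

    @property
    def size(self) -> int:
        """Number of edges."""
        return len(self.edges)

    def neighbors(self, v: int) -> tuple[int, ...]:
        return self.adjacency[v]

    @cached_property
    def temperatures(self) -> tuple[Fraction, ...]:
        """Exact vertex temperatures ``T_i = sum_{j~i} 1/d_j``.

        Their sum is always the order N: each edge {i,j} contributes
        1/d_j + 1/d_i, so summing over vertices counts every degree
        reciprocal exactly d_j times.
        """
        deg = self.degrees
        return tuple(
            sum((Fraction(1, deg[j - 1]) for j in self.adjacency[v]), Fraction(0))
            for v in range(1, self.order + 1)
        )

    @property
    def is_regular(self) -> bool:
        return len(set(self.degrees)) == 1

    @property
    def is_isothermal(self) -> bool:
        """Equal temperatures; for undirected graphs this equals regularity."""
        return len(set(self.temperatures)) == 1

    # -- canonical identification -----------------------------------------

    def _to_igraph(self) -> _ig.Graph:
        return _ig.Graph(self.order, [(i - 1, j - 1) for i, j in self.edges])

    @cached_property
    def canonical_edges(self) -> tuple[tuple[int, int], ...]:
        """Edges after canonical (isomorphism-invariant) relabelling, 1-based."""
        g = self._to_igraph()
        perm = g.canonical_permutation()
        g2 = g.permute_vertices(perm)
        return tuple(sorted(tuple(sorted((e.source + 1, e.target + 1))) for e in g2.es))

    @cached_property
    def canonical_id(self) -> int:
        """Isomorphism-invariant 64-bit id.

        The id is a sentinel bit ``2**C(N,2)`` plus the upper-triangle bits of
        the canonically labelled adjacency matrix; pair (i, j), i < j, in
        row-major order occupies the k-th least significant bit.  The sentinel
        makes the order recoverable from the id alone.
        """
        n = self.order
        if n > MAX_ID_ORDER:
            raise ValueError(
                f"canonical ids support order <= {MAX_ID_ORDER} (64-bit limit)")
        pos = {}
        k = 0
        for i in range(1, n + 1):
            for j in range(i + 1, n + 1):
                pos[(i, j)] = k
                k += 1
        bits = 1 << comb(n, 2)
        for e in self.canonical_edges:
            bits |= 1 << pos[e]
        return bits

    def automorphism_generators(self) -> list[tuple[int, ...]]:
        """Generators of the automorphism group as 0-based permutation tuples."""
        gens = self._to_igraph().automorphism_group()
        return [tuple(p) for p in gens]

    def isomorphic(self, other: "UndirectedGraph") -> bool:
        return (self.order == other.order
                and self._to_igraph().isomorphic(other._to_igraph()))

    # -- serialization ------------------------------------------------------

    def to_graph6(self) -> str:
        g = _nx.Graph()
        g.add_nodes_from(range(self.order))
        g.add_edges_from((i - 1, j - 1) for i, j in self.edges)
        return _nx.to_graph6_bytes(g, header=False).decode().strip()

    @classmethod
    def from_graph6(cls, s: str, name: str = "") -> "UndirectedGraph":
        g = _nx.from_graph6_bytes(s.strip().encode())
        return cls([(i + 1, j + 1) for i, j in g.edges()],
                   order=g.number_of_nodes(), name=name)

    def to_edgelist(self) -> str:
        """Plain text: one ``i j`` pair per line, 1-based."""
        lines = [f"# order {self.order}"]
        lines += [f"{i} {j}" for i, j in sorted(self.edges)]
        return "\n".join(lines) + "\n"

    @classmethod
    def from_edgelist(cls, text: str, name: str = "") -> "UndirectedGraph":
        edges = []
        order = None
        for line in text.splitlines():
            line = line.strip()
            if line.startswith("#"):
                parts = line[1:].split()
                if len(parts) == 2 and parts[0] == "order":
                    order = int(parts[1])
                continue
            if not line:
                continue
            i, j = line.split()
            edges.append((int(i), int(j)))
        return cls(edges, order=order, name=name)

    def __repr__(self) -> str:
        tag = f" {self.name!r}" if self.name else ""
        return f"UndirectedGraph(N={self.order}, m={self.size}{tag})"


def decode_canonical_id(gid: int) -> UndirectedGraph:
    """Invert :attr:`UndirectedGraph.canonical_id`."""
    top = gid.bit_length() - 1
    for n in range(2, MAX_ID_ORDER + 1):
        if comb(n, 2) == top:
            break
    else:
        raise ValueError(f"no supported order has C(N,2) = {top}")
    edges = []
    k = 0
    for i in range(1, n + 1):
        for j in range(i + 1, n + 1):
            if (gid >> k) & 1:
                edges.append((i, j))
            k += 1
    return UndirectedGraph(edges, order=n)


# -- module-level helpers mirroring the graph methods -----------------------

def temperatures(G: UndirectedGraph) -> tuple[Fraction, ...]:
    """Exact vertex temperatures of ``G`` (see :class:`UndirectedGraph`)."""
    return G.temperatures


def is_isothermal(G: UndirectedGraph) -> bool:
    return G.is_isothermal


def canonical_id(G: UndirectedGraph) -> int:
    return G.canonical_id


# -- graph families ----------------------------------------------------------

def clique(N: int) -> UndirectedGraph:
    """Complete graph K_N."""
    if N < 2:
        raise GraphParameterError("clique needs N >= 2")
    return UndirectedGraph([(i, j) for i in range(1, N + 1)
                            for j in range(i + 1, N + 1)], order=N, name=f"K{N}")


def cycle(N: int) -> UndirectedGraph:
    if N < 3:
        raise GraphParameterError("cycle needs N >= 3")
    edges = [(i, i + 1) for i in range(1, N)] + [(1, N)]
    return UndirectedGraph(edges, order=N, name=f"C{N}")


def star(N: int) -> UndirectedGraph:
    """Star K_{1,N-1} with centre 1."""
    if N < 3:
        raise GraphParameterError("star needs N >= 3")
    return UndirectedGraph([(1, j) for j in range(2, N + 1)], order=N,
                           name=f"K1,{N - 1}")


def complete_bipartite(a: int, b: int) -> UndirectedGraph:
    if a < 1 or b < 1 or a + b < 2:
        raise GraphParameterError("complete bipartite needs part sizes >= 1")
    edges = [(i, a + j) for i in range(1, a + 1) for j in range(1, b + 1)]
    return UndirectedGraph(edges, order=a + b, name=f"K{a},{b}")


def ell_graph(N: int, n: int, m: int) -> UndirectedGraph:
    """The graph obtained from the clique K_{N-2} plus two adjacent extra
    vertices, one joined to ``n`` clique vertices, the other to ``m`` disjoint
    clique vertices.

    Balanced when n = m; the balanced graphs of even order with
    n + m = N - 2 are global suppressors of selection.  Because the clique is
    vertex-transitive the result is independent, up to isomorphism, of which
    disjoint vertex sets are chosen.
    """
    if n < 1 or m < 1:
        raise GraphParameterError("ell graph needs n >= 1 and m >= 1")
    if N < 5:
        raise GraphParameterError("ell graph needs N >= 5")
    if n + m > N - 2:
        raise GraphParameterError(
            f"ell graph needs n + m <= N - 2 (got n + m = {n + m} > {N - 2})")
    k = N - 2
    edges = [(i, j) for i in range(1, k + 1) for j in range(i + 1, k + 1)]
    u, v = N - 1, N
    edges.append((u, v))
    edges += [(u, i) for i in range(1, n + 1)]
    edges += [(v, i) for i in range(n + 1, n + m + 1)]
    return UndirectedGraph(edges, order=N, name=f"ell{N}^{{{n},{m}}}")


def friendship_cycle(N: int, m: int) -> UndirectedGraph:
    """Cycle C_{N-1} plus a central vertex joined to ``m`` disjoint pairs of
    cycle-adjacent vertices.

    The pairs are spread around the cycle as evenly as possible (pair ``k``
    starts at position ``floor(k * (N-1) / m)``); this maximal-spacing
    convention reproduces the order-7 graph whose amplifier-to-suppressor
    transition lies at r ~ 4.99.
    """
    ncyc = N - 1
    if ncyc < 3:
        raise GraphParameterError("friendship cycle needs a cycle length >= 3")
    if m < 1 or 2 * m > ncyc:
        raise GraphParameterError(
            f"friendship cycle needs 1 <= m and 2m <= N - 1 (got m = {m})")
    starts = [(k * ncyc) // m for k in range(m)]
    if len(set(starts)) != m or any(
            (b - a) % ncyc < 2 for a, b in zip(starts, starts[1:] + [starts[0] + ncyc])):
        # fall back to tight packing if rounding collides (small cycles)
        starts = [2 * k for k in range(m)]
    edges = [(i, i % ncyc + 1) for i in range(1, ncyc + 1)]
    c = N
    for s in starts:
        a = s + 1
        b = a % ncyc + 1
        edges += [(c, a), (c, b)]
    return UndirectedGraph(edges, order=N, name=f"FC{N}^{m}")


def friendship_star(N: int, m: int) -> UndirectedGraph:
    """Friendship star: k = m/2 disjoint base edges, each carrying two apex
    vertices — one apex private to its base edge and one apex shared by all
    base edges (the star centre, which thus lies in every second 3-clique).

    Two base neighbours share two different neighbours (their private apex
    and the centre); apexes are pairwise non-adjacent and adjacent to nothing
    but their base pair.  Requires m even and N = 3 * (m // 2) + 1.
    """
    if m < 2 or m % 2:
        raise GraphParameterError("friendship star needs an even m >= 2")
    k = m // 2  # base edges
    if N != 3 * k + 1:
        raise GraphParameterError(
            f"friendship star with m = {m} needs N = {3 * k + 1} (got {N})")
    centre = N
    edges = []
    nxt = 1
    for _ in range(k):
        a, b, apex = nxt, nxt + 1, nxt + 2
        nxt += 3
        edges += [(a, b), (a, apex), (b, apex), (a, centre), (b, centre)]
    return UndirectedGraph(edges, order=N, name=f"FS{N}^{m}")


def friendship_ribbon(N: int, m: int) -> UndirectedGraph:
    """Friendship ribbon: a chain of diamonds (two 3-cliques sharing an edge)
    linked through their degree-2 tips, so no vertex lies in more than two
    3-cliques.  The m // 2 diamonds of 4 vertices share m // 2 - 1 link
    vertices, so m even and N = 3 * (m // 2) + 1.
    """
    if m < 2 or m % 2:
        raise GraphParameterError("friendship ribbon needs an even m >= 2")
    k = m // 2  # diamonds
    if N != 3 * k + 1:
        raise GraphParameterError(
            f"friendship ribbon with m = {m} needs N = {4 * k - (k - 1)} (got {N})")
    edges = []
    tip = 1  # entry tip of current diamond
    nxt = 2
    for _ in range(k):
        a, b, out = nxt, nxt + 1, nxt + 2
        nxt += 3
        edges += [(a, b), (tip, a), (tip, b), (out, a), (out, b)]
        tip = out
    return UndirectedGraph(edges, order=N, name=f"FR{N}^{m}")


_FAMILIES = {
    "clique": lambda N, params: clique(N),
    "cycle": lambda N, params: cycle(N),
    "star": lambda N, params: star(N),
    "complete_bipartite": lambda N, params: complete_bipartite(*params),
    "ell": lambda N, params: ell_graph(N, *params),
    "friendship_cycle": lambda N, params: friendship_cycle(N, *params),
    "friendship_star": lambda N, params: friendship_star(N, *params),
    "friendship_ribbon": lambda N, params: friendship_ribbon(N, *params),
}


@dataclass(frozen=True)
class FamilySpec:
    """Named graph family with order and family-specific parameters."""

    family: str
    order: int
    params: tuple[int, ...] = ()

    def __post_init__(self):
        if self.family not in _FAMILIES:
            raise GraphParameterError(
                f"unknown family {self.family!r}; choose from {sorted(_FAMILIES)}")


def make_family(spec: FamilySpec) -> UndirectedGraph:
    """Construct the graph described by ``spec``."""
    return _FAMILIES[spec.family](spec.order, tuple(spec.params))
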