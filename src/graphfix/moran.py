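"""The Moran Birth-Death process on a graph: states, transition kernel,
fixation linear system, and its exact / floating-point solution.

States of the chain are the vertex subsets S occupied by mutants, encoded as
N-bit integers (bit i-1 set iff vertex i is mutant).  At each step an
individual reproduces with probability proportional to fitness (r for
mutants, 1 for residents) and its offspring replaces a uniformly chosen
neighbour: the replacement weight from i to j is w_ij = 1/d_i.  The total
reproductive weight in state S is

    w_S(r) = r |S| + N - |S|.

The fixation probabilities Phi_S(r) solve a linear system over the
non-absorbing states; multiplying the equation of each state by w_S(r) clears
all denominators in r and leaves a square system whose entries are degree-one
polynomials in r with rational coefficients.  That cleared system is the
single object everything else in this package is computed from: evaluated at
a numeric r it is solved by LU factorisation, kept symbolic it yields the
exact rational fixation function.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from math import gcd, lcm
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np

from .graph import UndirectedGraph

__all__ = [
    "MutantConfiguration",
    "weight_matrix",
    "transition_row",
    "PolynomialLinearSystem",
    "build_polynomial_system",
    "FixationVector",
    "solve_fixation",
    "solve_fixation_grid",
    "OrbitReduction",
    "orbit_reduce",
]

ArithmeticMode = Literal["float", "exact", "highprec"]

try:  # gmpy2 rationals are ~5x faster than Fraction for dense elimination
    from gmpy2 import mpq as _mpq
except ImportError:  # pragma: no cover - gmpy2 ships with the sympy stack
    _mpq = Fraction


# -- states ------------------------------------------------------------------

@dataclass(frozen=True)
class MutantConfiguration:
    """A mutant-occupied vertex set, encoded as an N-bit integer."""

    encoding: int
    order: int

    def __post_init__(self):
        if not 0 <= self.encoding < (1 << self.order):
            raise ValueError("encoding out of range for this order")

    @classmethod
    def from_vertices(cls, vertices: Iterable[int], order: int) -> "MutantConfiguration":
        enc = 0
        for v in vertices:
            enc |= 1 << (v - 1)
        return cls(enc, order)

    @property
    def vertices(self) -> tuple[int, ...]:
        return tuple(v for v in range(1, self.order + 1)
                     if (self.encoding >> (v - 1)) & 1)

    @property
    def size(self) -> int:
        return self.encoding.bit_count()

    @property
    def is_absorbing(self) -> bool:
        return self.encoding == 0 or self.encoding == (1 << self.order) - 1


def weight_matrix(G: UndirectedGraph) -> list[list[Fraction]]:
    """Replacement weights w_ij = 1/d_i for j ~ i (exact rationals).

    Every row sums to one: reproduction always places the offspring on some
    neighbour.
    """
    N = G.order
    deg = G.degrees
    W = [[Fraction(0)] * N for _ in range(N)]
    for v in range(1, N + 1):
        for w in G.adjacency[v]:
            W[v - 1][w - 1] = Fraction(1, deg[v - 1])
    return W


def transition_row(G: UndirectedGraph, S: int | MutantConfiguration,
                   r: Fraction | int | float) -> dict[int, Fraction]:
    """One row of the transition kernel: probabilities from state ``S`` to
    each reachable state (including ``S`` itself), exact rationals.

    ``r`` must be positive; it is coerced to an exact rational so the row sums
    to one exactly.
    """
    if isinstance(S, MutantConfiguration):
        S = S.encoding
    r = Fraction(r)
    if r <= 0:
        raise ValueError("fitness r must be positive")
    N = G.order
    deg = G.degrees
    full = (1 << N) - 1
    wS = r * S.bit_count() + (N - S.bit_count())
    row: dict[int, Fraction] = {}
    stay = Fraction(0)
    for j in range(1, N + 1):
        jb = 1 << (j - 1)
        if S & jb:
            # resident i outside S replaces mutant j
            w = sum((Fraction(1, deg[i - 1]) for i in G.adjacency[j]
                     if not (S >> (i - 1)) & 1), Fraction(0))
            if w:
                row[S ^ jb] = row.get(S ^ jb, Fraction(0)) + w / wS
            # mutant i inside S replaces mutant j: state unchanged
            stay += r * sum((Fraction(1, deg[i - 1]) for i in G.adjacency[j]
                             if (S >> (i - 1)) & 1), Fraction(0))
        else:
            # mutant i inside S replaces resident j
            w = r * sum((Fraction(1, deg[i - 1]) for i in G.adjacency[j]
                         if (S >> (i - 1)) & 1), Fraction(0))
            if w:
                row[S | jb] = row.get(S | jb, Fraction(0)) + w / wS
            stay += sum((Fraction(1, deg[i - 1]) for i in G.adjacency[j]
                         if not (S >> (i - 1)) & 1), Fraction(0))
    if stay:
        row[S] = row.get(S, Fraction(0)) + stay / wS
    return row


# -- the cleared polynomial system ------------------------------------------

@dataclass
class PolynomialLinearSystem:
    """The cleared fixation system  Q*(r) Psi = c*(r)  with degree-one
    polynomial entries.

    The integer arrays store ``row_scale[k]`` times the cleared entries, i.e.
    ``q*(r)[k, l] = (A[k, l] + r B[k, l]) / row_scale[k]`` and likewise for
    the absorption columns ``c*`` (into full occupation) and ``b*`` (into
    extinction, kept for validation).  ``row_scale`` collects the vertex-degree
    least common multiple used to make every coefficient an integer, divided
    by any common integer factor of the row.

    ``states`` are the non-absorbing subset encodings (or orbit
    representatives for a lumped system, in which case ``multiplicity`` holds
    the number of singleton states in each orbit).
    """

    order: int
    states: tuple[int, ...]
    index: dict[int, int]
    A: np.ndarray
    B: np.ndarray
    c0: np.ndarray
    c1: np.ndarray
    b0: np.ndarray
    b1: np.ndarray
    row_scale: tuple[Fraction, ...]
    singleton_weight: np.ndarray  # u-vector: per-row number of singletons
    lumped: bool = False

    @property
    def n(self) -> int:
        return len(self.states)

    def q_star(self, k: int, l: int) -> tuple[Fraction, Fraction]:
        """(constant, r-coefficient) of entry (k, l) of Q*(r)."""
        s = self.row_scale[k]
        return (Fraction(int(self.A[k, l])) / s, Fraction(int(self.B[k, l])) / s)

    def c_star(self, k: int) -> tuple[Fraction, Fraction]:
        s = self.row_scale[k]
        return (Fraction(int(self.c0[k])) / s, Fraction(int(self.c1[k])) / s)

    def b_star(self, k: int) -> tuple[Fraction, Fraction]:
        s = self.row_scale[k]
        return (Fraction(int(self.b0[k])) / s, Fraction(int(self.b1[k])) / s)

    def evaluated(self, r: Fraction | float):
        """Dense (Q*(r), c*(r)) with float entries at numeric ``r``."""
        r = float(r)
        return (self.A + r * self.B, self.c0 + r * self.c1)


def _orbit_partition(G: UndirectedGraph) -> tuple[np.ndarray, list[int]]:
    """Partition of all 2^N subsets into automorphism orbits.

    Returns (orbit index per subset, representative subset per orbit); the
    representative is the smallest encoding in its orbit.
    """
    N = G.order
    gens = G.automorphism_generators()
    total = 1 << N
    orbit = np.full(total, -1, dtype=np.int64)
    reps: list[int] = []
    if not gens:
        orbit[:] = np.arange(total)
        return orbit, list(range(total))
    # permutation action on subsets via bit scatter
    for s in range(total):
        if orbit[s] >= 0:
            continue
        oid = len(reps)
        reps.append(s)
        stack = [s]
        orbit[s] = oid
        while stack:
            t = stack.pop()
            for g in gens:
                img = 0
                tt = t
                while tt:
                    b = tt & -tt
                    img |= 1 << g[b.bit_length() - 1]
                    tt ^= b
                if orbit[img] < 0:
                    orbit[img] = oid
                    stack.append(img)
    return orbit, reps


def build_polynomial_system(G: UndirectedGraph, lumped: bool = False
                            ) -> PolynomialLinearSystem:
    """Assemble the cleared fixation system over non-absorbing states.

    With ``lumped=True`` the system is built over automorphism orbits of
    subsets (exact lumping: orbit-mates have identical fixation
    probabilities), which can shrink the 2^N - 2 states dramatically for
    symmetric graphs.
    """
    N = G.order
    if N > 20:
        raise ValueError("state space 2^N exceeds practical memory bounds; "
                         "use a lumped system or a larger machine")
    deg = G.degrees
    adj = G.adjacency
    L = lcm(*deg)
    full = (1 << N) - 1

    if lumped:
        orbit, reps = _orbit_partition(G)
        states = tuple(s for s in reps if s not in (0, full))
        col_of = {}
        oid_to_col = {}
        k = 0
        for s in states:
            oid_to_col[int(orbit[s])] = k
            k += 1
        def col(t: int) -> int | None:
            if t == 0 or t == full:
                return None
            return oid_to_col[int(orbit[t])]
    else:
        states = tuple(range(1, full))
        def col(t: int) -> int | None:
            if t == 0 or t == full:
                return None
            return t - 1

    index = {s: k for k, s in enumerate(states)}
    n = len(states)
    A = np.zeros((n, n), dtype=np.int64)
    B = np.zeros((n, n), dtype=np.int64)
    c0 = np.zeros(n, dtype=np.int64)
    c1 = np.zeros(n, dtype=np.int64)
    b0 = np.zeros(n, dtype=np.int64)
    b1 = np.zeros(n, dtype=np.int64)
    scales: list[Fraction] = []

    for k, s in enumerate(states):
        size = s.bit_count()
        selfA = 0
        selfB = 0
        for j in range(1, N + 1):
            jb = 1 << (j - 1)
            if s & jb:
                w = sum(L // deg[i - 1] for i in adj[j] if not (s >> (i - 1)) & 1)
                t = s ^ jb
                if t == 0:
                    b0[k] += w
                else:
                    A[k, col(t)] -= w
                selfB += sum(L // deg[i - 1] for i in adj[j] if (s >> (i - 1)) & 1)
            else:
                w = sum(L // deg[i - 1] for i in adj[j] if (s >> (i - 1)) & 1)
                t = s | jb
                if t == full:
                    c1[k] += w
                else:
                    B[k, col(t)] -= w
                selfA += sum(L // deg[i - 1] for i in adj[j] if not (s >> (i - 1)) & 1)
        A[k, k] += (N - size) * L - selfA
        B[k, k] += size * L - selfB
        g = gcd(int(c0[k]), int(c1[k]), int(b0[k]), int(b1[k]),
                *(int(x) for x in A[k]), *(int(x) for x in B[k]))
        if g > 1:
            A[k] //= g
            B[k] //= g
            c0[k] //= g
            c1[k] //= g
            b0[k] //= g
            b1[k] //= g
        scales.append(Fraction(L, g if g > 1 else 1))

    u = np.zeros(n, dtype=np.int64)
    for v in range(N):
        c = col(1 << v)
        u[c] += 1

    return PolynomialLinearSystem(
        order=N, states=states, index=index, A=A, B=B,
        c0=c0, c1=c1, b0=b0, b1=b1, row_scale=tuple(scales),
        singleton_weight=u, lumped=lumped)


# -- solving -----------------------------------------------------------------

@dataclass
class FixationVector:
    """Per-state fixation probabilities at one fitness value."""

    fitness: object
    arithmetic_mode: str
    psi: Mapping[int, object]          # non-absorbing state -> Phi_S(r)
    singles: tuple
    average: object
    order: int

    def __getitem__(self, state: int):
        full = (1 << self.order) - 1
        if state == 0:
            return type(self.average)(0) if not isinstance(self.average, float) else 0.0
        if state == full:
            return type(self.average)(1) if not isinstance(self.average, float) else 1.0
        return self.psi[state]


def _exact_solve(sys_: PolynomialLinearSystem, r) -> list:
    """Gaussian elimination over exact rationals on (A + r B) x = c0 + r c1."""
    rq = _mpq(r.numerator, r.denominator) if isinstance(r, Fraction) else _mpq(r)
    n = sys_.n
    Aint, Bint = sys_.A, sys_.B
    M = [[_mpq(int(Aint[i, j])) + rq * int(Bint[i, j]) for j in range(n)]
         for i in range(n)]
    rhs = [_mpq(int(sys_.c0[i])) + rq * int(sys_.c1[i]) for i in range(n)]
    for i in range(n):
        p = i
        while M[p][i] == 0:
            p += 1
        if p != i:
            M[i], M[p] = M[p], M[i]
            rhs[i], rhs[p] = rhs[p], rhs[i]
        inv = 1 / M[i][i]
        for j in range(i, n):
            M[i][j] *= inv
        rhs[i] *= inv
        for k in range(i + 1, n):
            f = M[k][i]
            if f:
                for j in range(i + 1, n):
                    M[k][j] -= f * M[i][j]
                rhs[k] -= f * rhs[i]
                M[k][i] = _mpq(0)
    x = [_mpq(0)] * n
    for i in range(n - 1, -1, -1):
        s = rhs[i]
        Mi = M[i]
        for j in range(i + 1, n):
            if Mi[j]:
                s -= Mi[j] * x[j]
        x[i] = s
    return [Fraction(v.numerator, v.denominator) for v in x]


def _highprec_solve(sys_: PolynomialLinearSystem, r, digits: int) -> list:
    import mpmath
    with mpmath.workdps(digits):
        rr = mpmath.mpf(r.numerator) / mpmath.mpf(r.denominator) \
            if isinstance(r, Fraction) else mpmath.mpf(r)
        n = sys_.n
        M = mpmath.matrix(n, n)
        rhs = mpmath.matrix(n, 1)
        for i in range(n):
            for j in range(n):
                M[i, j] = int(sys_.A[i, j]) + rr * int(sys_.B[i, j])
            rhs[i] = int(sys_.c0[i]) + rr * int(sys_.c1[i])
        x = mpmath.lu_solve(M, rhs)
        return [x[i] for i in range(n)]


def solve_fixation(G: UndirectedGraph, r, mode: ArithmeticMode = "float",
                   digits: int = 50, lumped: bool = False,
                   system: PolynomialLinearSystem | None = None) -> FixationVector:
    """Solve the fixation system of ``G`` at fitness ``r``.

    Modes: ``float`` uses partial-pivoting LU on the cleared system evaluated
    at r (the fast path); ``exact`` uses rational elimination and requires a
    rational r; ``highprec`` uses an mpmath LU at ``digits`` significant
    digits, for sign decisions too delicate for doubles.

    Returns per-state, per-singleton and average fixation probabilities.  At
    r = 1 the average is exactly 1/N in exact mode (neutral drift).
    """
    if isinstance(r, (int, Fraction)):
        rfrac = Fraction(r)
    elif mode == "exact":
        raise TypeError("exact mode needs a rational fitness value")
    else:
        rfrac = None
    if (rfrac if rfrac is not None else r) <= 0:
        raise ValueError("fitness r must be positive")
    sys_ = system if system is not None else build_polynomial_system(G, lumped=lumped)
    if mode == "exact":
        x = _exact_solve(sys_, rfrac)
    elif mode == "highprec":
        x = _highprec_solve(sys_, rfrac if rfrac is not None else r, digits)
    elif mode == "float":
        M, c = sys_.evaluated(float(r))
        x = list(np.linalg.solve(M.astype(float), c.astype(float)))
    else:
        raise ValueError(f"unknown arithmetic mode {mode!r}")

    N = G.order
    if sys_.lumped:
        orbit, reps = _orbit_partition(G)
        rep_col = {}
        for s, k in sys_.index.items():
            rep_col[int(orbit[s])] = k
        psi = {s: x[rep_col[int(orbit[s])]] for s in range(1, (1 << N) - 1)}
    else:
        psi = {s: x[k] for s, k in sys_.index.items()}
    singles = tuple(psi[1 << (v - 1)] for v in range(1, N + 1))
    if mode == "float":
        avg = float(sum(singles) / N)
    elif mode == "exact":
        avg = sum(singles, Fraction(0)) / N
    else:
        avg = sum(singles) / N
    return FixationVector(fitness=r if rfrac is None else rfrac,
                          arithmetic_mode=mode, psi=psi, singles=singles,
                          average=avg, order=N)


def solve_fixation_grid(G: UndirectedGraph, rs: Sequence[float],
                        system: PolynomialLinearSystem | None = None,
                        chunk: int = 64) -> np.ndarray:
    """Average fixation probability at many fitness values by batched LU.

    Stacks (Q*(r), c*(r)) for a chunk of grid values and lets LAPACK solve
    them together; returns an array aligned with ``rs``.
    """
    sys_ = system if system is not None else build_polynomial_system(G)
    A = sys_.A.astype(float)
    B = sys_.B.astype(float)
    c0 = sys_.c0.astype(float)
    c1 = sys_.c1.astype(float)
    u = sys_.singleton_weight.astype(float) / G.order
    out = np.empty(len(rs), dtype=float)
    rs = np.asarray(rs, dtype=float)
    for lo in range(0, len(rs), chunk):
        sub = rs[lo:lo + chunk]
        M = A[None, :, :] + sub[:, None, None] * B[None, :, :]
        c = c0[None, :] + sub[:, None] * c1[None, :]
        x = np.linalg.solve(M, c[:, :, None])[:, :, 0]
        out[lo:lo + chunk] = x @ u
    return out


# -- orbit reduction ----------------------------------------------------------

@dataclass
class OrbitReduction:
    """Lumping of the subset chain by the automorphism group of the graph."""

    orbit_of: np.ndarray               # subset encoding -> orbit id
    representatives: tuple[int, ...]   # orbit id -> smallest subset encoding
    reduced_system: PolynomialLinearSystem

    @property
    def n_orbits(self) -> int:
        return len(self.representatives)


def orbit_reduce(G: UndirectedGraph) -> OrbitReduction:
    """Reduce the fixation system over automorphism orbits of mutant sets.

    Vertices in the same orbit of the automorphism group have equal fixation
    probabilities, and more generally the chain restricted to subset orbits
    is exactly lumpable: for any two states in one orbit the total transition
    weight into any other orbit is identical (the group permutes the
    transition targets).  Solving the reduced system and expanding back gives
    the full fixation vector exactly.
    """
    orbit, reps = _orbit_partition(G)
    return OrbitReduction(orbit_of=orbit, representatives=tuple(reps),
                          reduced_system=build_polynomial_system(G, lumped=True))
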