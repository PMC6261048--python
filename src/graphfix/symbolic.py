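"""Exact rational-function fixation curves Phi(r) = Phi'(r) / Phi''(r).

Fixation probabilities of the Moran Birth-Death chain are rational functions
of the fitness with rational coefficients, of degree at most the number of
non-absorbing states (2^N - 2, or the orbit count after symmetry lumping).
Two routes produce the canonical coprime representation:

``points``
    The evaluation/interpolation scheme: solve the fixation system exactly at
    the fitness values {1, ..., d+1} and {1/2, ..., 1/d}, then solve the 2d
    linear equations for the coefficients with the leading coefficients of
    numerator and denominator pinned to 1 (Phi -> 1 as r -> infinity).  When
    numerator and denominator share a factor the interpolation system is rank
    deficient; the degree bound is reduced until the solution is unique,
    which is exactly the canonical coprime representation.

``resolvent``
    The modular route of :mod:`graphfix._modular`, far faster for large
    state spaces.

Both are validated against a fresh exact solve at a fitness value that took
no part in the computation.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from math import gcd
from typing import Literal

import sympy as sp

from .graph import UndirectedGraph
from .moran import PolynomialLinearSystem, build_polynomial_system, solve_fixation

__all__ = ["RationalFunction", "interpolate_fixation", "fixation_function"]

_r = sp.Symbol("r")


class PoleError(ZeroDivisionError):
    """Evaluation at a root of the denominator."""


@dataclass(frozen=True)
class RationalFunction:
    """A univariate rational function in canonical coprime form.

    The denominator is primitive over the integers with positive leading
    coefficient; the numerator carries exact rational coefficients.  For
    fixation curves the numerator is integer as well and the two leading
    coefficients agree (Phi(r) -> 1 at large fitness).
    """

    numerator: sp.Poly
    denominator: sp.Poly

    @classmethod
    def from_coeffs(cls, num, den) -> "RationalFunction":
        """Build from low-to-high coefficient sequences (ints / Fractions)."""
        pn = sp.Poly(list(reversed([sp.Rational(c) for c in num])), _r, domain="QQ")
        pd = sp.Poly(list(reversed([sp.Rational(c) for c in den])), _r, domain="QQ")
        return cls._canonical(pn, pd)

    @classmethod
    def from_expr(cls, expr) -> "RationalFunction":
        num, den = sp.fraction(sp.cancel(sp.together(sp.sympify(expr))))
        return cls._canonical(sp.Poly(num, _r, domain="QQ"),
                              sp.Poly(den, _r, domain="QQ"))

    @classmethod
    def _canonical(cls, pn: sp.Poly, pd: sp.Poly) -> "RationalFunction":
        if pd.is_zero:
            raise ZeroDivisionError("zero denominator")
        if pn.is_zero:
            return cls(sp.Poly(0, _r, domain="QQ"), sp.Poly(1, _r, domain="QQ"))
        g = pn.gcd(pd)
        if g.degree() > 0:
            pn = pn.quo(g)
            pd = pd.quo(g)
        # denominator primitive over ZZ, positive leading coefficient
        cont_d = sp.Rational(pd.content())
        if pd.LC() < 0:
            cont_d = -cont_d
        pn = sp.Poly(pn / cont_d, _r, domain="QQ")
        pd = sp.Poly(pd / cont_d, _r, domain="QQ")
        return cls(pn, pd)

    # -- arithmetic --------------------------------------------------------

    def __add__(self, other: "RationalFunction") -> "RationalFunction":
        return RationalFunction._canonical(
            self.numerator * other.denominator + other.numerator * self.denominator,
            self.denominator * other.denominator)

    def __sub__(self, other: "RationalFunction") -> "RationalFunction":
        return RationalFunction._canonical(
            self.numerator * other.denominator - other.numerator * self.denominator,
            self.denominator * other.denominator)

    def __neg__(self) -> "RationalFunction":
        return RationalFunction(-self.numerator, self.denominator)

    def __eq__(self, other) -> bool:
        if not isinstance(other, RationalFunction):
            return NotImplemented
        return (self.numerator == other.numerator
                and self.denominator == other.denominator)

    def __hash__(self):
        return hash((self.numerator, self.denominator))

    def diff(self, n: int = 1) -> "RationalFunction":
        out = self
        for _ in range(n):
            out = RationalFunction._canonical(
                out.numerator.diff(_r) * out.denominator
                - out.numerator * out.denominator.diff(_r),
                out.denominator * out.denominator)
        return out

    @property
    def degree(self) -> int:
        return max(self.numerator.degree(), self.denominator.degree())

    @property
    def is_zero(self) -> bool:
        return self.numerator.is_zero

    def __call__(self, x):
        """Evaluate; exact for int/Fraction/sympy input, float for float."""
        if isinstance(x, float):
            return float(self.numerator.eval(x)) / float(self.denominator.eval(x))
        xq = sp.Rational(Fraction(x)) if not isinstance(x, sp.Basic) else x
        den = self.denominator.eval(xq)
        if den == 0:
            raise PoleError(f"pole at r = {x}")
        v = self.numerator.eval(xq) / den
        return Fraction(int(v.p), int(v.q)) if isinstance(v, sp.Rational) else v

    def as_expr(self):
        return self.numerator.as_expr() / self.denominator.as_expr()

    def coeff_strings(self) -> tuple[list[str], list[str]]:
        """Low-to-high exact coefficient strings (for serialization)."""
        num = [str(sp.nsimplify(c)) for c in reversed(self.numerator.all_coeffs())]
        den = [str(sp.nsimplify(c)) for c in reversed(self.denominator.all_coeffs())]
        return num, den

    def __repr__(self):
        return f"RationalFunction(({self.numerator.as_expr()}) / ({self.denominator.as_expr()}))"


def _interpolation_points(d: int) -> list[Fraction]:
    pts = [Fraction(k) for k in range(1, d + 2)]
    pts += [Fraction(1, k) for k in range(2, d + 1)]
    # keep exactly 2d distinct points, extend with unused integers if short
    nxt = d + 2
    while len(pts) < 2 * d:
        pts.append(Fraction(nxt))
        nxt += 1
    return pts[:2 * d]


def _solve_rational_linear(M: list[list[Fraction]], rhs: list[Fraction]
                           ) -> list[Fraction] | None:
    """Exact solve; None when the matrix is singular (rank deficient)."""
    n = len(M)
    M = [row[:] + [rhs[i]] for i, row in enumerate(M)]
    for i in range(n):
        p = i
        while p < n and M[p][i] == 0:
            p += 1
        if p == n:
            return None
        M[i], M[p] = M[p], M[i]
        inv = 1 / M[i][i]
        M[i] = [x * inv for x in M[i]]
        for k in range(n):
            if k != i and M[k][i]:
                f = M[k][i]
                M[k] = [a - f * b for a, b in zip(M[k], M[i])]
    return [M[i][n] for i in range(n)]


def interpolate_fixation(G: UndirectedGraph, degree_bound: int | None = None,
                         method: Literal["auto", "points", "resolvent"] = "auto",
                         system: PolynomialLinearSystem | None = None,
                         verify: bool = True) -> RationalFunction:
    """The exact average fixation probability of ``G`` as a rational function.

    ``degree_bound`` defaults to the number of non-absorbing subset orbits of
    the automorphism group (by Cramer's rule on the degree-one polynomial
    system, the determinant degree is at most the system size).  The
    ``points`` route follows the evaluation/interpolation scheme literally
    and is preferred for small systems; ``resolvent`` scales to the full
    order-7 state space and beyond.
    """
    if system is None:
        system = build_polynomial_system(G, lumped=True)
    n = system.n
    if method == "auto":
        method = "points" if n <= 16 else "resolvent"

    if method == "resolvent":
        from ._modular import fixation_polynomials
        pden, pnum = fixation_polynomials(system)
        rf = RationalFunction.from_coeffs(pnum, [G.order * c for c in pden])
    else:
        rf = _interpolate_by_points(G, system,
                                    degree_bound if degree_bound is not None else n)
    if verify:
        held_out = Fraction(4, 3)
        probe = solve_fixation(G, held_out, mode="exact", system=system)
        if rf(held_out) != probe.average:
            raise AssertionError(
                "interpolated fixation function failed held-out validation")
    return rf


def _interpolate_by_points(G: UndirectedGraph, system: PolynomialLinearSystem,
                           d: int) -> RationalFunction:
    # exact evaluations are reused as d decreases
    cache: dict[Fraction, Fraction] = {}

    def phi(pt: Fraction) -> Fraction:
        if pt not in cache:
            cache[pt] = solve_fixation(G, pt, mode="exact", system=system).average
        return cache[pt]

    while d >= 1:
        pts = _interpolation_points(d)
        # unknowns a_0..a_{d-1}, b_0..b_{d-1}; a_d = b_d = 1
        M: list[list[Fraction]] = []
        rhs: list[Fraction] = []
        for pt in pts:
            val = phi(pt)
            row = [pt ** i for i in range(d)]
            row += [-val * pt ** i for i in range(d)]
            M.append(row)
            rhs.append(val * pt ** d - pt ** d)
        sol = _solve_rational_linear(M, rhs)
        if sol is not None:
            num = sol[:d] + [Fraction(1)]
            den = sol[d:] + [Fraction(1)]
            rf = RationalFunction.from_coeffs(num, den)
            # rank-deficiency can hide behind special point choices; accept
            # only if an unused point confirms the function
            probe = Fraction(2 * d + 5, 2)
            if rf(probe) == phi(probe):
                return rf
        d -= 1
    raise RuntimeError("interpolation failed at every degree bound "
                       "(internal solver inconsistency)")


def fixation_function(G: UndirectedGraph, **kw) -> RationalFunction:
    """Alias for :func:`interpolate_fixation`."""
    return interpolate_fixation(G, **kw)
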