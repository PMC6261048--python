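"""Evolutionary regimes: the homogeneous baselines Phi0 and Phi2, exact sign
analysis of D(r) = Phi(r) - Phi0(r) on (1, oo), transition isolation, and
regime classification.

A connected graph of order N with average fixation probability Phi(r) is

* *isothermal*  when Phi(r) = Phi0(r) identically (exactly the regular
  graphs, by the Isothermal Theorem),
* an *amplifier of selection* on an interval of r > 1 when Phi(r) > Phi0(r)
  there, and a *suppressor* when Phi(r) < Phi0(r),
* said to have a *transition* at r_c > 1 when D changes sign there.

The exact method forms the integer polynomial

    M(r) = Phi'(r) (r^N - 1) - N' Phi''(r) r^{N-1} (r - 1)

whose sign equals the sign of D on (1, oo) (both cleared denominators are
positive there), strips the root at r = 1, and isolates the remaining real
roots.  Roots of even multiplicity are tangencies, not transitions: the
regime does not change.  Classification on r < 1 is not attempted (the
advantageous-mutant case is the object of study); the solver itself is happy
with any positive fitness.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Literal, Sequence

import sympy as sp

from .graph import UndirectedGraph
from .moran import build_polynomial_system, solve_fixation, solve_fixation_grid
from .symbolic import RationalFunction, interpolate_fixation

__all__ = [
    "phi0", "phi0_value", "phi2", "phi2_value",
    "ReferenceCurves", "reference_curves",
    "TransitionRecord", "RegimeProfile",
    "classify", "isolate_transitions", "fixation_difference",
    "phi0_concavity", "ConcavityReport",
    "STANDARD_GRID", "EXTENDED_GRID",
]

_r = sp.Symbol("r")

#: the fitness grids used by the numeric scan
STANDARD_GRID: tuple[float, ...] = tuple(0.25 * k for k in range(1, 41))
EXTENDED_GRID: tuple[float, ...] = tuple(float(k) for k in range(11, 2001))


# -- reference curves --------------------------------------------------------

def phi0(N: int) -> RationalFunction:
    """Fixation probability of a single advantageous mutant in a homogeneous
    population of size N:  Phi0(r) = (1 - 1/r) / (1 - r^-N).

    In canonical coprime form the removable singularity at r = 1 is gone:
    Phi0(r) = r^{N-1} / (r^{N-1} + ... + r + 1), and Phi0(1) = 1/N.
    """
    if N < 2:
        raise ValueError("population size N >= 2 required")
    num = [0] * (N - 1) + [1]
    den = [1] * N
    return RationalFunction.from_coeffs(num, den)


def phi0_value(N: int, r) -> Fraction | float:
    return phi0(N)(r)


def phi2(N: int) -> RationalFunction:
    """The star/complete-bipartite upper bound Phi2(r) = Phi0(r^2)."""
    base = phi0(N)
    num = base.numerator.as_expr().subs(_r, _r ** 2)
    den = base.denominator.as_expr().subs(_r, _r ** 2)
    return RationalFunction._canonical(sp.Poly(num, _r, domain="QQ"),
                                       sp.Poly(den, _r, domain="QQ"))


def phi2_value(N: int, r) -> Fraction | float:
    return phi2(N)(r)


@dataclass(frozen=True)
class ReferenceCurves:
    order: int
    phi0: RationalFunction
    phi2: RationalFunction


def reference_curves(N: int) -> ReferenceCurves:
    return ReferenceCurves(order=N, phi0=phi0(N), phi2=phi2(N))


# -- transitions -------------------------------------------------------------

@dataclass(frozen=True)
class TransitionRecord:
    """A sign change of D = Phi - Phi0 at a critical fitness r_c > 1.

    ``interval`` is an exact isolating rational interval of width below
    1e-6 containing the single odd-multiplicity root; ``direction`` is
    "S/A" when the graph switches from suppressor to amplifier (D goes
    - to +) and "A/S" for the reverse.
    """

    interval: tuple[Fraction, Fraction]
    direction: Literal["S/A", "A/S"]

    @property
    def r_c(self) -> float:
        return float((self.interval[0] + self.interval[1]) / 2)

    @property
    def r_c_2dp(self) -> float:
        """Two-decimal display value, truncated (the source convention for
        '~' critical values)."""
        return int(self.r_c * 100) / 100


@dataclass(frozen=True)
class RegimeProfile:
    """Regime structure of a graph on the advantageous range (1, oo)."""

    classification: Literal["isothermal", "amplifier", "suppressor", "multi-regime"]
    sequence: tuple[str, ...]          # regime letters between transitions
    transitions: tuple[TransitionRecord, ...]
    method: Literal["exact", "numeric-scan"]
    scan_signs: tuple[int, ...] | None = None
    scan_grid: tuple[float, ...] | None = None
    inconclusive: bool = False

    @property
    def pattern(self) -> str:
        """Slash-joined regime sequence, e.g. ``"S/A"``; empty if isothermal."""
        return "/".join(self.sequence)


def _sign(x) -> int:
    if x > 0:
        return 1
    if x < 0:
        return -1
    return 0


def _poly_sign_at(P: sp.Poly, x: Fraction) -> int:
    v = P.eval(sp.Rational(x.numerator, x.denominator))
    return 1 if v > 0 else (-1 if v < 0 else 0)


def _strip_root_at_one(P: sp.Poly) -> sp.Poly:
    one = sp.Poly([1, -1], _r, domain="ZZ")
    while P.eval(1) == 0 and P.degree() > 0:
        P = P.quo(one)
    return P


def isolate_transitions(D: RationalFunction,
                        max_width: Fraction = Fraction(1, 10 ** 6)
                        ) -> list[TransitionRecord]:
    """Odd-multiplicity real roots of the numerator of ``D`` in (1, oo).

    ``D`` must be a difference of fixation curves in canonical form; its
    denominator is positive on (1, oo), so the sign of D equals the sign of
    its numerator there.  Returns transitions sorted by increasing r_c, each
    with an isolating interval no wider than ``max_width``.
    """
    if D.is_zero:
        return []
    num = D.numerator
    # scale to integer coefficients
    denlcm = sp.lcm([sp.Rational(c).q for c in num.all_coeffs()])
    P = sp.Poly(num * denlcm, _r, domain="ZZ")
    if D.denominator.eval(1) < 0 or _has_positive_root(
            sp.Poly(D.denominator, _r).shift(1)):
        raise ValueError("denominator of D is not positive on (1, oo)")
    P = _strip_root_at_one(P)
    Psq = P.quo(P.gcd(P.diff(_r)))
    shifted = Psq.shift(1)  # roots > 0 of shifted <-> roots > 1 of P
    signs = [c for c in shifted.all_coeffs() if c != 0]
    variations = sum(1 for a, b in zip(signs, signs[1:]) if (a > 0) != (b > 0))
    if variations == 0:
        return []
    records: list[TransitionRecord] = []
    for (a, b), _mult in shifted.intervals(inf=0):
        if b <= 0:
            continue
        lo, hi = Fraction(int(a.p), int(a.q)), Fraction(int(b.p), int(b.q))
        if lo == hi:
            # exact rational root: perturb outward for sign probing
            eps = Fraction(1, 10 ** 9)
            s_lo = _poly_sign_at(P, lo + 1 - eps)
            s_hi = _poly_sign_at(P, hi + 1 + eps)
            lo, hi = lo - eps, hi + eps
        else:
            s_lo = _poly_sign_at(P, lo + 1)
            s_hi = _poly_sign_at(P, hi + 1)
        if s_lo == 0 or s_hi == 0 or s_lo == s_hi:
            if s_lo != 0 and s_lo == s_hi:
                continue  # even multiplicity: tangency, no regime change
            raise RuntimeError("could not certify interval endpoint signs")
        # bisect on the squarefree shifted polynomial
        slo_sq = _poly_sign_at(shifted, lo)
        while hi - lo > max_width:
            mid = (lo + hi) / 2
            sm = _poly_sign_at(shifted, mid)
            if sm == 0:
                half = max_width / 2
                lo, hi = mid - half, mid + half
                break
            if sm == slo_sq:
                lo = mid
            else:
                hi = mid
        direction = "S/A" if (s_lo, s_hi) == (-1, 1) else "A/S"
        records.append(TransitionRecord(interval=(lo + 1, hi + 1),
                                        direction=direction))
    records.sort(key=lambda t: t.interval[0])
    return records


def _has_positive_root(P: sp.Poly) -> bool:
    signs = [c for c in P.all_coeffs() if c != 0]
    variations = sum(1 for a, b in zip(signs, signs[1:]) if (a > 0) != (b > 0))
    if variations == 0:
        return False
    return bool(P.intervals(inf=0))


def fixation_difference(G: UndirectedGraph, **kw) -> RationalFunction:
    """D(r) = Phi(r) - Phi0(r) in canonical coprime form."""
    return interpolate_fixation(G, **kw) - phi0(G.order)


# -- classification ----------------------------------------------------------

def classify(G: UndirectedGraph,
             method: Literal["exact", "numeric-scan"] = "exact",
             grid: Sequence[float] = STANDARD_GRID,
             extended_grid: Sequence[float] = EXTENDED_GRID,
             rf_method: Literal["auto", "points", "resolvent"] = "auto",
             ) -> RegimeProfile:
    """Determine the evolutionary regime structure of ``G`` on (1, oo).

    The exact method certifies the full regime sequence from the canonical
    rational fixation function.  The numeric scan reports the *apparent*
    regime on a fitness grid (re-solving at 50 digits where |D| falls under
    1e-9) and extends the grid to r = 2000 when the pattern could still
    change; its verdict is only as good as its scan range.

    Regularity is checked first: regular graphs are isothermal by the
    Isothermal Theorem, with no root isolation at all.
    """
    if G.is_regular:
        return RegimeProfile(classification="isothermal", sequence=(),
                             transitions=(), method="exact")
    if method == "exact":
        rf = interpolate_fixation(G, method=rf_method, verify=False)
        # cheap independent cross-check of the exact function against the
        # floating-point solver (guards against assembly-level mistakes)
        fl = solve_fixation(G, 2.0, mode="float").average
        if abs(rf(2.0) - fl) > 1e-8 * abs(fl):
            raise AssertionError(
                "exact fixation function disagrees with the numeric solver")
        D = rf - phi0(G.order)
        if D.is_zero:  # cannot happen for non-regular graphs; keep honest
            return RegimeProfile(classification="isothermal", sequence=(),
                                 transitions=(), method="exact")
        trans = tuple(isolate_transitions(D))
        # sample one interior sign per interval, exactly
        bounds = [Fraction(1)] + [t.interval[1] for t in trans]
        seq = []
        num = D.numerator
        for i, lo in enumerate(bounds):
            hi = trans[i].interval[0] if i < len(trans) else lo + 1
            probe = (lo + hi) / 2 if i < len(trans) else lo + 1
            s = _sign(D(probe))
            seq.append("A" if s > 0 else "S")
        if not trans:
            cls = "amplifier" if seq[0] == "A" else "suppressor"
        else:
            cls = "multi-regime"
        return RegimeProfile(classification=cls, sequence=tuple(seq),
                             transitions=trans, method="exact")
    return _classify_scan(G, grid, extended_grid)


def _classify_scan(G: UndirectedGraph, grid, extended_grid) -> RegimeProfile:
    system = build_polynomial_system(G)
    base = phi0(G.order)
    rs = [x for x in grid if x > 1]
    signs, inconclusive = _grid_signs(G, system, base, rs)
    collapsed = _collapse(signs)
    # extend when the tail could still flip: any pattern is provisional, but
    # tail-sensitive patterns (A-endings, ambiguity) need the longer range
    if len(extended_grid):
        rs2 = list(extended_grid)
        s2, inc2 = _grid_signs(G, system, base, rs2)
        signs = signs + s2
        rs = rs + rs2
        inconclusive = inconclusive or inc2
        collapsed = _collapse(signs)
    seq = tuple(x for x in collapsed if x != "0")
    transitions: tuple = ()
    # locate apparent sign flips for reporting (grid-resolution intervals)
    recs = []
    for i in range(1, len(signs)):
        if signs[i - 1] != 0 and signs[i] != 0 and signs[i] != signs[i - 1]:
            lo, hi = Fraction(rs[i - 1]).limit_denominator(10 ** 6), \
                Fraction(rs[i]).limit_denominator(10 ** 6)
            recs.append(TransitionRecord(
                interval=(lo, hi),
                direction="S/A" if signs[i] > 0 else "A/S"))
    transitions = tuple(recs)
    if not seq:
        cls = "isothermal"
    elif len(seq) == 1:
        cls = "amplifier" if seq[0] == "A" else "suppressor"
    else:
        cls = "multi-regime"
    return RegimeProfile(classification=cls, sequence=seq,
                         transitions=transitions, method="numeric-scan",
                         scan_signs=tuple(signs),
                         scan_grid=tuple(float(x) for x in rs),
                         inconclusive=inconclusive)


def _grid_signs(G, system, base, rs) -> tuple[list[int], bool]:
    import mpmath
    vals = solve_fixation_grid(G, rs, system=system)
    signs = []
    inconclusive = False
    for r, v in zip(rs, vals):
        d = v - base(float(r))
        if abs(d) >= 1e-9:
            signs.append(1 if d > 0 else -1)
            continue
        # delicate: re-solve at 50 significant digits
        rq = Fraction(r).limit_denominator(10 ** 9)
        fv = solve_fixation(G, rq, mode="highprec", digits=50, system=system)
        b = base(rq)
        diff = fv.average - mpmath.mpf(b.numerator) / mpmath.mpf(b.denominator)
        if abs(diff) > mpmath.mpf(10) ** (-30):
            signs.append(1 if diff > 0 else -1)
        else:
            signs.append(0)
            inconclusive = True
    return signs, inconclusive


def _collapse(signs) -> str:
    out = []
    for s in signs:
        c = "A" if s > 0 else ("S" if s < 0 else "0")
        if not out or out[-1] != c:
            out.append(c)
    return "".join(out)


# -- concavity of the baseline ----------------------------------------------

@dataclass(frozen=True)
class ConcavityReport:
    order: int
    concave_on_advantageous_range: bool
    convex_witness: Fraction | None = None  # a point in (1, oo) with Phi0'' > 0


def phi0_concavity(N: int) -> ConcavityReport:
    """Whether Phi0 is concave on all of (1, oo).

    True exactly for N in {2, 3, 4, 5}; from N = 6 on, Phi0 is convex just
    above r = 1 and only becomes concave further out.  For the non-concave
    case a certified rational witness point with positive second derivative
    is returned.
    """
    second = phi0(N).diff(2)
    num = second.numerator
    denlcm = sp.lcm([sp.Rational(c).q for c in num.all_coeffs()])
    P = sp.Poly(num * denlcm, _r, domain="ZZ")
    # Phi0'' < 0 for large r always; concavity on (1, oo) means the shifted
    # numerator has no positive sign changes
    shifted = P.shift(1)
    if not _has_positive_root(shifted) and _poly_sign_at(P, Fraction(2)) < 0:
        return ConcavityReport(order=N, concave_on_advantageous_range=True)
    # find a rational witness close to 1 with Phi0''(w) > 0
    k = 2
    while k < 10 ** 9:
        w = 1 + Fraction(1, k)
        if _poly_sign_at(P, w) > 0 and second.denominator.eval(
                sp.Rational(w.numerator, w.denominator)) > 0:
            return ConcavityReport(order=N, concave_on_advantageous_range=False,
                                   convex_witness=w)
        k *= 2
    raise RuntimeError("no convexity witness found near r = 1")
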