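# Methods

## Model

The Moran Birth-Death process on a simple connected undirected graph G with
vertices V = {1, …, N}: states are the mutant-occupied subsets S ⊆ V.  With
replacement weights w_ij = 1/d_i for neighbours (rows of W sum to one) and
total reproductive weight w_S(r) = r|S| + N − |S|, one step either adds a
vertex j (a mutant i ∈ S reproduces into j, probability r Σ_{i∈S} w_ij /
w_S), removes a vertex j (a resident reproduces into j ∈ S), or leaves S
unchanged.  Extinction (S = ∅) and fixation (S = V) absorb.  The fixation
probabilities Φ_S(r) satisfy a linear system over the 2^N − 2 non-absorbing
states; the *average* fixation probability Φ(r) uses a uniformly random
initial single mutant (Birth-Death updating with uniform initialisation
throughout; temperature-weighted initialisation and Death-Birth updating are
out of scope).  Classification compares Φ with the homogeneous baseline
Φ₀(r) = r^{N−1}(r−1)/(r^N−1) on the advantageous range r > 1 only; the
solvers accept any r > 0.

## The cleared system

Multiplying the balance equation of each state by w_S(r) produces
Q*(r)·Ψ(r) = c*(r) whose entries are degree-one polynomials in r with
rational coefficients.  Internally each row is additionally scaled by
L = lcm(d_1, …, d_N) divided by the row's integer content, making every
coefficient a machine integer; the per-row scale factors are retained so the
rational Q* entries remain exactly recoverable (`PolynomialLinearSystem`).
The extinction column b*(r) is kept alongside c*(r) and used in tests: row
entries plus both absorption columns must total w_S(r) exactly (cleared
row-stochasticity).

Three solvers act on this object:

* **float** — LAPACK LU on Q*(r) evaluated at numeric r; a batched variant
  stacks many grid values per call.
* **exact** — Gaussian elimination over exact rationals (gmpy2 `mpq` when
  available, `fractions.Fraction` otherwise); requires rational r.
* **highprec** — mpmath LU at a requested number of significant digits
  (default 50), used by the numeric scan when |Φ − Φ₀| < 1e−9 so sign
  decisions never rest on doubles.  If a float factorisation ever failed
  outright the same escalation path applies.

## Automorphism lumping

Vertices in one orbit of Aut(G) have equal fixation probabilities, and the
subset chain is exactly lumpable over subset orbits: group elements permute
transition targets, so the aggregate weight from any orbit member into any
other orbit is state-independent (tested explicitly).  Orbits are computed
from BLISS automorphism generators (igraph) acting on bitmask subsets; the
lumped system is assembled directly over orbit representatives, with the
singleton-orbit multiplicities as the averaging vector.  For highly
symmetric families this is dramatic — the order-10 friendship star drops
from 1022 states to 110 — and it also lowers the degree bound of the
rational fixation function.

## Exact rational fixation functions

Two independent routes produce the canonical coprime Φ′/Φ″ (denominator
primitive over ℤ with positive leading coefficient; for fixation curves the
leading coefficients of numerator and denominator then agree, since
Φ → 1 as r → ∞):

1. **Evaluation–interpolation** (`symbolic.interpolate_fixation`,
   `method="points"`).  With degree bound d (the lumped orbit count), Φ is
   solved exactly at r ∈ {1, …, d+1} ∪ {1/2, …, 1/d} and the 2d linear
   equations for the coefficients (leading coefficients pinned to 1) are
   solved over the rationals.  A singular system means numerator and
   denominator share a factor; d is reduced until the solution is unique,
   which is precisely the canonical representation.  If a reduced d would
   collide sample points, the smallest unused integers are appended.  The
   result is validated against a fresh exact solve at r = 4/3, a point no
   route ever samples.

2. **Modular resolvent** (`_modular.fixation_polynomials`,
   `method="resolvent"`).  Writing the integer-scaled system as A + rB,
   Pden(r) = det(A + rB) and Pnum(r) = uᵀ adj(A + rB)(c₀ + r c₁) are integer
   polynomials with Φ = Pnum/(N·Pden).  Both A and B are invertible over ℚ
   (each is a weakly chained diagonally dominant M-matrix: every state
   chains to an absorbing move), so modulo a 31-bit prime
   det(A + rB) = det(A)·det(I + rM) with M = A⁻¹B, det(I + rM) is read off
   the characteristic polynomial of M (Hessenberg reduction), and the
   adjugate follows the recurrence P_k = d_k I − M P_{k−1}, which turns all
   numerator coefficients into dot products against the Krylov rows uᵀMʲ.
   One O(n³) pass per prime — no evaluation points — then coefficient
   recovery by Chinese remaindering with symmetric representatives.
   Reconstruction is accepted only when (i) it is unchanged from the
   previous prime, (ii) the modulus has ≥ 40 bits of headroom over the
   largest coefficient, and (iii) two exact structural identities hold:
   Pnum(1) = Pden(1) (neutral fixation is exactly 1/N) and
   lead(Pnum) = N·lead(Pden).  Exact classification additionally
   cross-checks the function against the independent float solver at r = 2.
   Order-7 coefficients reach ~950 bits (≈ 31 primes); a 126-state graph
   takes ~0.2–0.4 s.

Both routes agree exactly on every graph where both run (tested), and both
agree with a brute-force Fraction solver built independently in the test
suite from the raw stochastic system.

## Transition isolation

For D = Φ − Φ₀ the sign on (1, ∞) equals the sign of the integer polynomial
M(r) = numerator(D) (denominators are positive there; positivity of the
denominator is itself checked by Descartes' rule on the shifted polynomial).
The factor (r−1)^k is stripped, the square-free part is formed by exact gcd,
and the shift r ↦ r+1 gives a Descartes count: zero sign variations
certifies "no transitions" with no further work (the common case — most
graphs are global amplifiers).  Otherwise the real roots in (0, ∞) of the
shifted square-free polynomial are isolated (sympy's interval isolation) and
refined by bisection with exact rational sign evaluations to width ≤ 1e−6.
A root is a transition only if the full (non-square-free) numerator changes
sign across its interval; even-multiplicity roots are tangencies and are
discarded.  Regime letters between transitions come from exact evaluation
of D at a rational interior point of each interval, so the reported
sequence alternates by construction of the root set.

Two-decimal summaries (`r_c_2dp`) truncate the third decimal rather than
round — the convention the reference critical values are printed with
(e.g. the root 5.1761… prints as 5.17); full-precision floats and the exact
isolating intervals are always retained alongside.

## Numeric scan mode

The scan evaluates D on the grid r = 0.25(0.25)10 and the extended grid
10(1)2000 with the batched float solver, escalating to the 50-digit solver
whenever |D| < 1e−9 and declaring a grid point inconclusive (never silently
signed) if even the high-precision difference lies under 1e−30.  Scan
verdicts are *apparent* by nature and carry their grid; in the census,
scan-mode graphs whose pattern shows any transition or inconclusive point
are re-classified by the exact route (default for orders ≤ 8).  Exact mode
is the authority for all order ≤ 7 results.

## Enumeration and counting

Connected graphs are enumerated order by order: every connected graph on N
vertices arises from one on N−1 by attaching a vertex to a non-empty
neighbourhood (a DFS-tree leaf can always be deleted), so augmenting all
order-(N−1) representatives and deduplicating by canonical form (BLISS) is
complete.  Orders ≤ 7 take under a second, order 8 a few seconds.
Census order is ascending canonical id, making output deterministic and
checkpoint-resumable byte-identically.  Per-order class counts up to order
10 come from Burnside counting over the pair action of S_N (cycle-index
evaluation per partition) followed by the inverse Euler transform that
extracts connected counts; the two methods agree wherever both apply, and
the orders 2–10 total is 11,989,763.

The canonical 64-bit id is a sentinel bit 2^C(N,2) plus the upper-triangle
bits of the canonically labelled adjacency matrix (row-major pair order).
It decodes back to the graph and supports N ≤ 10.  It is *not* the id
scheme of the published fixation database, whose bit layout is not public;
database graphs are matched by isomorphism instead.

## Monte-Carlo simulator

Used exclusively to validate the solvers, never to classify.  Each
trajectory samples the reproducing individual by total-weight inversion
(weight r|S| + N − |S|) and the replaced neighbour uniformly — equivalent,
by construction, to the subset-chain kernel — and runs to absorption.
Randomness comes from counter-based splitmix64 streams keyed by (seed, run
index), so estimates are exactly reproducible and independent of batching.
A 10⁸-step cap per trajectory guards the (almost surely finite) absorption
loop; hitting it raises, since it can only indicate a bug.  Estimates carry
binomial standard errors; agreement tests use a 3.29σ band.

## Problem sizes and defaults

The shipped tests and the acceptance script run the exact censuses of
orders 6 (112 graphs, seconds) and 7 (853 graphs, a few minutes), the
ℓ-graph and friendship-family critical values, and the counting identity
through order 10.  The order-8 census (11,117 graphs) is supported through
the same API — numeric scan with exact confirmation of every flagged graph —
as an optional longer run; orders 9–10 are counted but not enumerated here.

## Known limitations

* Exact symbolic curves are practical up to a few hundred (lumped) states;
  beyond that the numeric scan is the only route, and its regime calls are
  apparent, limited to its grid (transitions beyond r = 2000 would be
  missed — exactly the caveat the scan mode records).
* The friendship star/ribbon constructors implement one concrete convention
  (shared-apex books; tip-linked diamond chains) chosen because it
  reproduces every independently checkable critical value (FS₇⁴, FS₁₀⁶,
  FR₁₀⁶, FC₇²–FC₁₀³); other graphs answering the same verbal description
  exist.
* Directed graphs, weighted replacement beyond w_ij = 1/d_i, Death-Birth
  updating, fixation times, and regime taxonomy for r < 1 are out of scope.
* The modular route's prime budget certifies coefficients up to ~3700 bits;
  larger systems raise `PrimeBudgetError` rather than silently truncating.
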