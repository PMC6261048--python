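"""Exact computation of the fixation rational function by modular algebra.

The average fixation probability of a graph is

    Phi(r) = u^T (A + r B)^{-1} (c0 + r c1) / N
           = Pnum(r) / (N * Pden(r)),

where (A + r B) is the integer-scaled cleared fixation system,
Pden(r) = det(A + r B) and Pnum(r) = u^T adj(A + r B) (c0 + r c1) are integer
polynomials of degree at most n (the number of non-absorbing states or
orbits).  Both are computed modulo a sequence of 31-bit primes — with no
evaluation points: writing M = A^{-1}B over GF(p),

    det(A + r B) = det(A) * det(I + r M),

det(I + r M) is read off the characteristic polynomial of M (Hessenberg
reduction), and the adjugate satisfies the Horner-style recurrence
P_k = d_k I - M P_{k-1}, so all numerator coefficients come from the Krylov
row sequence u^T M^j.  One O(n^3) pass per prime replaces the ~2n exact
rational solves a pointwise interpolation would need.

Coefficients are recovered by Chinese remaindering with symmetric
representatives.  Reconstruction is accepted only when it is stable under an
additional prime, has >= 40 bits of modulus headroom, and satisfies two exact
structural identities of fixation functions: Pnum(1) = Pden(1)
(neutral fixation is exactly 1/N) and lead(Pnum) = N * lead(Pden)
(fixation tends to 1 as r grows).  For delicate downstream uses the result
can additionally be verified against an independent exact rational solve at
a held-out fitness value.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["fixation_polynomials", "PrimeBudgetError"]


class PrimeBudgetError(RuntimeError):
    """Coefficient reconstruction did not stabilise within the prime budget."""


def _gen_primes(count: int = 120) -> tuple[int, ...]:
    import sympy
    out = []
    p = 1 << 31
    while len(out) < count:
        p = int(sympy.prevprime(p))
        out.append(p)
    return tuple(out)


_PRIMES: tuple[int, ...] | None = None


def _primes() -> tuple[int, ...]:
    global _PRIMES
    if _PRIMES is None:
        _PRIMES = _gen_primes()
    return _PRIMES


@njit(cache=True)
def _modinv(a, p):
    res = 1
    b = a % p
    e = p - 2
    while e:
        if e & 1:
            res = res * b % p
        b = b * b % p
        e >>= 1
    return res


@njit(cache=True)
def _resolvent_modp(A, B, c0, c1, u, p):  # pragma: no cover - jitted
    """Coefficients of (Pden, Pnum) mod p; length-1 arrays flag a bad prime."""
    n = A.shape[0]
    bad = np.zeros(1, dtype=np.int64)
    m = n + 2
    W = np.empty((n, n + m), dtype=np.int64)
    for i in range(n):
        for j in range(n):
            W[i, j] = A[i, j] % p
            W[i, n + j] = B[i, j] % p
        W[i, n + n] = c0[i] % p
        W[i, n + n + 1] = c1[i] % p
    detA = 1
    for i in range(n):
        piv = -1
        for k in range(i, n):
            if W[k, i] != 0:
                piv = k
                break
        if piv < 0:
            return bad, bad
        if piv != i:
            for j in range(n + m):
                t = W[i, j]
                W[i, j] = W[piv, j]
                W[piv, j] = t
            detA = (p - detA) % p
        d = W[i, i]
        detA = detA * d % p
        dinv = _modinv(d, p)
        for j in range(i, n + m):
            W[i, j] = W[i, j] * dinv % p
        for k in range(n):
            if k != i and W[k, i] != 0:
                f = p - W[k, i]
                for j in range(i, n + m):
                    W[k, j] = (W[k, j] + f * W[i, j]) % p
    M = W[:, n:2 * n].copy()
    v = W[:, 2 * n].copy()
    w = W[:, 2 * n + 1].copy()

    # Hessenberg reduction of M over GF(p)
    H = M.copy()
    for i in range(1, n - 1):
        piv = -1
        for k in range(i, n):
            if H[k, i - 1] != 0:
                piv = k
                break
        if piv < 0:
            continue
        if piv != i:
            for j in range(n):
                t = H[i, j]
                H[i, j] = H[piv, j]
                H[piv, j] = t
            for j in range(n):
                t = H[j, i]
                H[j, i] = H[j, piv]
                H[j, piv] = t
        hinv = _modinv(H[i, i - 1], p)
        for k in range(i + 1, n):
            if H[k, i - 1] != 0:
                f = H[k, i - 1] * hinv % p
                fneg = (p - f) % p
                for j in range(n):
                    H[k, j] = (H[k, j] + fneg * H[i, j]) % p
                for j in range(n):
                    H[j, i] = (H[j, i] + f * H[j, k]) % p

    # characteristic polynomials of leading Hessenberg blocks
    polys = np.zeros((n + 1, n + 1), dtype=np.int64)
    polys[0, 0] = 1
    for k in range(1, n + 1):
        a = H[k - 1, k - 1] % p
        an = (p - a) % p
        for j in range(k):
            polys[k, j + 1] = (polys[k, j + 1] + polys[k - 1, j]) % p
            polys[k, j] = (polys[k, j] + an * polys[k - 1, j]) % p
        prod = 1
        for i in range(k - 2, -1, -1):
            prod = prod * H[i + 1, i] % p
            if prod == 0:
                break
            hik = H[i, k - 1] % p
            if hik != 0:
                f = (p - hik * prod % p) % p
                for j in range(i + 1):
                    polys[k, j] = (polys[k, j] + f * polys[i, j]) % p
    q = polys[n]

    # det(I + r M) from the characteristic polynomial
    dI = np.zeros(n + 1, dtype=np.int64)
    for k in range(n + 1):
        s = q[k] % p
        if (n + k) % 2 == 1:
            s = (p - s) % p
        dI[n - k] = s
    pden = np.zeros(n + 1, dtype=np.int64)
    for k in range(n + 1):
        pden[k] = dI[k] * detA % p

    # Krylov row sequence u^T M^j against v and w
    y = u.astype(np.int64) % p
    alpha = np.zeros(n, dtype=np.int64)
    beta = np.zeros(n, dtype=np.int64)
    for j in range(n):
        s1 = 0
        s2 = 0
        for t in range(n):
            s1 = (s1 + y[t] * v[t]) % p
            s2 = (s2 + y[t] * w[t]) % p
        alpha[j] = s1
        beta[j] = s2
        if j < n - 1:
            ynew = np.zeros(n, dtype=np.int64)
            for t in range(n):
                yt = y[t]
                if yt != 0:
                    for jj in range(n):
                        ynew[jj] = (ynew[jj] + yt * M[t, jj]) % p
            y = ynew

    # z_k = u^T P_k with P_k = d_k I - M P_{k-1}
    zv = np.zeros(n, dtype=np.int64)
    zw = np.zeros(n, dtype=np.int64)
    for k in range(n):
        s1 = 0
        s2 = 0
        for j in range(k + 1):
            dcf = dI[k - j]
            if j % 2 == 0:
                s1 = (s1 + dcf * alpha[j]) % p
                s2 = (s2 + dcf * beta[j]) % p
            else:
                s1 = (s1 + (p - dcf) * alpha[j]) % p
                s2 = (s2 + (p - dcf) * beta[j]) % p
        zv[k] = s1
        zw[k] = s2
    pnum = np.zeros(n + 1, dtype=np.int64)
    for k in range(n + 1):
        s = 0
        if k < n:
            s = zv[k]
        if k >= 1:
            s = (s + zw[k - 1]) % p
        pnum[k] = s * detA % p
    return pden, pnum


def fixation_polynomials(system, min_primes: int = 3,
                         headroom_bits: int = 40) -> tuple[list[int], list[int]]:
    """Integer coefficient lists (low to high) of (Pden, Pnum) for a
    :class:`~graphfix.moran.PolynomialLinearSystem`.

    ``Phi(r) = Pnum(r) / (N * Pden(r))``.  Raises :class:`PrimeBudgetError`
    if the coefficients do not stabilise (this indicates a solver bug, not an
    input problem: the prime budget covers coefficients far beyond the sizes
    occurring for supported orders).
    """
    N = system.order
    A, B = system.A, system.B
    c0, c1 = system.c0, system.c1
    u = system.singleton_weight
    vd: list[int] | None = None
    vn: list[int] | None = None
    modulus = 1
    nprimes = 0
    prev_key = None
    for p in _primes():
        pd, pn = _resolvent_modp(A, B, c0, c1, u, p)
        if len(pd) == 1:
            continue  # singular A modulo this prime: discard it
        nprimes += 1
        if modulus == 1:
            vd = [int(x) for x in pd]
            vn = [int(x) for x in pn]
            modulus = p
        else:
            inv = pow(modulus % p, p - 2, p)
            new_mod = modulus * p
            for vec, arr in ((vd, pd), (vn, pn)):
                for i in range(len(vec)):
                    d = (int(arr[i]) - vec[i]) % p
                    if d:
                        vec[i] = (vec[i] + modulus * (d * inv % p)) % new_mod
            modulus = new_mod
        if nprimes >= min_primes:
            half = modulus >> 1
            sd = [x - modulus if x > half else x for x in vd]
            sn = [x - modulus if x > half else x for x in vn]
            big = max(abs(x) for x in sd + sn)
            key = (tuple(sd), tuple(sn))
            if (key == prev_key
                    and sum(sn) == sum(sd)
                    and sn[-1] == N * sd[-1]
                    and big.bit_length() < modulus.bit_length() - headroom_bits):
                return sd, sn
            prev_key = key
    raise PrimeBudgetError(
        "fixation polynomial coefficients did not stabilise; "
        "this indicates an internal solver inconsistency")
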