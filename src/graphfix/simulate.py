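"""Monte-Carlo simulation of Moran Birth-Death trajectories.

This module exists purely as an independent stochastic oracle for the linear
solvers: it samples the same transition kernel by direct simulation and
reports binomial estimates with standard errors.  It is never used to
classify regimes — simulation on a bounded fitness window cannot certify a
regime that only changes at larger fitness.

Each trajectory draws its own random stream from a counter-based splitmix64
seeded by (seed, run index), so results are reproducible and independent of
run order or batching.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import sqrt

import numpy as np
from numba import njit

from .graph import UndirectedGraph

__all__ = ["SimulationEstimate", "estimate_fixation", "per_vertex_fixation"]

_STEP_CAP = 100_000_000  # absorption is a.s. finite; hitting this is a bug


@dataclass(frozen=True)
class SimulationEstimate:
    """Binomial fixation estimate from independent trajectories."""

    runs: int
    fixations: int
    estimate: float
    std_error: float
    seed: int

    def within(self, target: float, z: float = 3.29) -> bool:
        """Whether ``target`` lies inside the z-sigma band of the estimate."""
        se = self.std_error if self.std_error > 0 else 1.0 / self.runs
        return abs(self.estimate - target) <= z * se


@njit(cache=True, inline="always")
def _splitmix64(state):  # pragma: no cover - jitted
    state = (state + np.uint64(0x9E3779B97F4A7C15)) & np.uint64(0xFFFFFFFFFFFFFFFF)
    z = state
    z = ((z ^ (z >> np.uint64(30))) * np.uint64(0xBF58476D1CE4E5B9)) & np.uint64(0xFFFFFFFFFFFFFFFF)
    z = ((z ^ (z >> np.uint64(27))) * np.uint64(0x94D049BB133111EB)) & np.uint64(0xFFFFFFFFFFFFFFFF)
    z = z ^ (z >> np.uint64(31))
    return state, z


@njit(cache=True)
def _run_batch(adj, deg, N, r, runs, seed, init_vertex, cap):  # pragma: no cover
    """Count fixations over ``runs`` trajectories.

    init_vertex < 0 draws the initial mutant uniformly; otherwise every
    trajectory starts at that 0-based vertex.  Returns (fixations,
    per-initial-vertex fixations, per-initial-vertex starts, capped runs).
    """
    fix = 0
    fix_by_v = np.zeros(N, dtype=np.int64)
    starts_by_v = np.zeros(N, dtype=np.int64)
    capped = 0
    mutant = np.zeros(N, dtype=np.uint8)
    for run in range(runs):
        state = (np.uint64(seed) << np.uint64(20)) ^ np.uint64(run)
        # warm the stream
        state, z = _splitmix64(state)
        state, z = _splitmix64(state)
        if init_vertex >= 0:
            v0 = np.int64(init_vertex)
        else:
            state, z = _splitmix64(state)
            v0 = np.int64(z % np.uint64(N))
        starts_by_v[v0] += 1
        for i in range(N):
            mutant[i] = 0
        mutant[v0] = 1
        k = 1  # mutant count
        steps = 0
        while 0 < k < N and steps < cap:
            steps += 1
            # reproducer: total weight r*k + (N - k)
            total = r * k + (N - k)
            state, z = _splitmix64(state)
            x = (float(z) / 18446744073709551616.0) * total
            if x < r * k:
                # pick the ceil(x/r)-th mutant
                target = int(x / r)
                if target >= k:
                    target = k - 1
                idx = -1
                c = -1
                for i in range(N):
                    if mutant[i]:
                        c += 1
                        if c == target:
                            idx = i
                            break
                rep_is_mutant = True
            else:
                target = int(x - r * k)
                if target >= N - k:
                    target = N - k - 1
                idx = -1
                c = -1
                for i in range(N):
                    if not mutant[i]:
                        c += 1
                        if c == target:
                            idx = i
                            break
                rep_is_mutant = False
            # offspring replaces a uniform neighbour
            state, z = _splitmix64(state)
            j = adj[idx, np.int64(z % np.uint64(deg[idx]))]
            if mutant[j] and not rep_is_mutant:
                mutant[j] = 0
                k -= 1
            elif not mutant[j] and rep_is_mutant:
                mutant[j] = 1
                k += 1
        if steps >= cap:
            capped += 1
        elif k == N:
            fix += 1
            fix_by_v[v0] += 1
    return fix, fix_by_v, starts_by_v, capped


def _packed_adjacency(G: UndirectedGraph):
    N = G.order
    deg = np.array(G.degrees, dtype=np.int64)
    adj = np.zeros((N, int(deg.max())), dtype=np.int64)
    for v in range(1, N + 1):
        for k, w in enumerate(G.adjacency[v]):
            adj[v - 1, k] = w - 1
    return adj, deg


def estimate_fixation(G: UndirectedGraph, r: float, runs: int, seed: int,
                      initial: int | None = None) -> SimulationEstimate:
    """Estimate the fixation probability by ``runs`` independent trajectories.

    ``initial`` is a 1-based starting vertex; by default the initial mutant
    is placed uniformly at random (the averaging convention of the model).
    """
    if runs < 1:
        raise ValueError("runs >= 1 required")
    if r <= 0:
        raise ValueError("fitness r must be positive")
    adj, deg = _packed_adjacency(G)
    init = -1 if initial is None else initial - 1
    fix, _, _, capped = _run_batch(adj, deg, G.order, float(r), runs,
                                   seed, init, _STEP_CAP)
    if capped:
        raise RuntimeError(
            f"{capped} trajectories hit the step cap; absorption is almost "
            "surely finite, so this indicates a simulator bug")
    p = fix / runs
    return SimulationEstimate(runs=runs, fixations=fix, estimate=p,
                              std_error=sqrt(p * (1 - p) / runs), seed=seed)


def per_vertex_fixation(G: UndirectedGraph, r: float, runs: int, seed: int
                        ) -> dict[int, SimulationEstimate]:
    """Fixation estimates conditioned on the initial vertex, from one pooled
    uniformly-initialised run (for coverage checks against solver values)."""
    adj, deg = _packed_adjacency(G)
    fix, fix_by_v, starts_by_v, capped = _run_batch(
        adj, deg, G.order, float(r), runs, seed, -1, _STEP_CAP)
    if capped:
        raise RuntimeError("step cap hit; simulator bug")
    out = {}
    for v in range(G.order):
        n_v = int(starts_by_v[v])
        f_v = int(fix_by_v[v])
        p = f_v / n_v if n_v else float("nan")
        out[v + 1] = SimulationEstimate(
            runs=n_v, fixations=f_v, estimate=p,
            std_error=sqrt(p * (1 - p) / n_v) if n_v else float("inf"),
            seed=seed)
    return out
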