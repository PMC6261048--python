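# graphfix

Exact fixation probabilities and evolutionary regimes of the Moran
Birth-Death process on small undirected graphs.

## The problem

A population occupies the vertices of a connected undirected graph G on
N vertices; a single mutant with relative fitness r appears on a uniformly
random vertex.  Each time step one individual reproduces (chosen with
probability proportional to fitness: r for mutants, 1 for residents) and its
offspring replaces a uniformly chosen neighbour.  The chain ends in
extinction or *fixation*; the **fixation probability** Φ(r) is the central
quantity of evolutionary graph theory.  For the homogeneous (complete-graph)
population,

    Φ₀(r) = (1 − r⁻¹) / (1 − r⁻ᴺ).

Graph structure can help or hinder the mutant: a graph is an **amplifier of
selection** where Φ(r) > Φ₀(r) (r > 1), a **suppressor** where Φ(r) < Φ₀(r),
and **isothermal** — Φ ≡ Φ₀ — exactly when it is regular (Isothermal
Theorem).  Some graphs *switch* regime at critical fitness values r_c, which
simulation alone can neither locate precisely nor even count reliably.

graphfix is for researchers who need **certified** answers for small graphs:
it computes Φ(r) as an exact rational function Φ′(r)/Φ″(r) with rational
coefficients, isolates every sign change of Φ − Φ₀ on (1, ∞) by exact root
isolation, and runs exhaustive per-order censuses of all connected graphs up
to isomorphism.

## What is inside

* `graphfix.graph` — graph construction (ℓ-graphs, friendship
  cycles/stars/ribbons, stars, cliques, cycles, complete bipartite),
  vertex temperatures, isomorphism-invariant 64-bit ids, graph6/edge-list IO.
* `graphfix.enumeration` — one representative per isomorphism class of
  connected graphs (orders ≤ 8), plus cycle-index counting up to order 10.
* `graphfix.moran` — the subset-state chain, the cleared linear system
  Q*(r)·Ψ = c*(r) with degree-one polynomial entries, float / exact-rational
  / high-precision solvers, and exact lumping by graph automorphisms.
* `graphfix.symbolic` — canonical coprime rational fixation functions, by
  exact evaluation–interpolation or by a modular resolvent method that
  handles the full 126-state order-7 systems in well under a second.
* `graphfix.regimes` — Φ₀/Φ₂ reference curves, regime classification with
  certified transitions (exact) or grid scans (apparent), and the concavity
  facts for Φ₀ (concave on (1, ∞) only for N ≤ 5).
* `graphfix.census` — checkpointed, resumable per-order census with
  summaries and barcode (sign-pattern) export.
* `graphfix.simulate` — a reproducible Monte-Carlo trajectory sampler, used
  purely as an independent stochastic oracle in the tests.

## A worked example

```python
>>> import graphfix as gf
>>> g = gf.ell_graph(7, 2, 2)        # K5 plus two linked vertices, each tied
...                                  # to its own pair of clique vertices
>>> prof = gf.classify(g)            # exact: rational function + root isolation
>>> prof.pattern
'S/A'
>>> [(t.direction, t.r_c_2dp) for t in prof.transitions]
[('S/A', 5.17)]
```

The graph is a suppressor of selection for 1 < r < r_c and an amplifier
beyond; the unique critical fitness r_c = 5.1761… is certified by isolating
the single odd-multiplicity root of the integer polynomial
Φ′(r)(r⁷−1) − 7Φ″(r)r⁶(r−1) on (1, ∞).  Two-decimal displays are truncated
(5.17, not 5.18), following the convention the reference values use.

The same from the shell:

```
$ graphfix classify --family ell --N 7 --param 2 --param 2 --exact
classification  multi-regime
pattern S/A
method  exact
transition      S/A     5.17
$ graphfix fixprob --graph6 A_ --r 2 --exact
average 2/3
```

Exhaustive censuses reproduce the published per-order tables; order 6 takes
seconds, order 7 minutes:

```
$ graphfix census --order 6 --method exact --out order6.tsv
112 graphs classified -> order6.tsv
$ graphfix summarize --in order6.tsv
order 6: total 112 isothermal 5 suppressor 1 amplifier 100 transitions [S/A:6] exact
```

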