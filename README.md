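# panchain

Co-linear chaining of exact-match anchors on **cyclic, string-labeled
pangenome graphs**.

Pangenome reference graphs represent the genetic diversity of a species
as a directed graph `G(V, E, σ)` whose vertices carry DNA string labels.
Inversions, duplications and copy-number variants make these graphs
*cyclic*, which breaks the topological-order dynamic programming that
sequence-to-graph aligners use for the chaining stage of
seed–chain–extend.  `panchain` implements an exact chaining algorithm
for graphs with cycles: it preprocesses the graph into a small path
cover with reachability and distance tables, then finds optimal anchor
chains with an iterative sparse DP whose per-pass work is
`O(N |P| log N)` for `N` anchors and cover size `|P|`.  An `O(N²)`
reference DP is included and every score the sparse algorithm produces
is testable against it.

It is a library first (importable API plus `examples/`), with a thin
`panchain` command-line tool for shell pipelines.

## The model

An **anchor** `(v, [x..y], [c..d])` records that `σ(v)[x..y]` exactly
matches query substring `Q[c..d]` (1-based inclusive, equal spans).
Anchor `a` **precedes** `b` iff `a.d < b.c` and either `a.v` reaches
`b.v` (different vertices), or on the same vertex `a.y < b.x` or the
vertex lies on a proper cycle (the chain loops back around).  A
**chain** is an ordered anchor subset under consecutive precedence; its
score is

```
Σ weight(s_j)  −  Σ gap_Q(s_j, s_{j+1})  −  Σ gap_G(s_j, s_{j+1})
```

with `gap_Q = s_{j+1}.c − s_j.d − 1` and `gap_G = s_{j+1}.x − s_j.y − 1`
plus a graph distance: the shortest-path distance in the exact model, or
the **path-cover-restricted distance** `D_P` in the fast model.  `D_P`
walks from the source vertex along a cover path up to `α` (the target
itself, or `last2reach(target, i)` — the last vertex on path `P_i` that
reaches the target) and finishes with a precomputed shortest path; it
always upper-bounds the true distance and is computable in `O(|P|)` per
pair.  Same-vertex loops are charged `D°_P(v)`, the length of the
shortest path-cover-restricted closed walk through `v`.

Preprocessing (per weak component): remove DFS back edges inside each
strongly connected component, cover the resulting DAG with a *minimum*
path cover via a minimum-flow reduction (the same reduction on the
cyclic graph yields a certified lower bound on any cover size), rank
vertices topologically, then fill the `last2reach` and distance tables
with label-propagation sweeps that converge in at most `|V|`
value-changing passes (`Γ_l`, `Γ_d` in practice 1–3).

Chaining: one range-maximum search tree per cover path, keyed by anchor
query end-points, holding a separable encoding of chain scores.  Each
pass executes a sorted task array (≤ `4 N |P|` tasks: interleaved
updates/queries at each anchor's vertex, after-vertex queries at
`last2reach`, and cycle-stage tasks on cyclic vertices) over vertices in
rank order.  On DAGs one pass is optimal; with cycles passes repeat to a
fixpoint, reached after at most `N` value-changing passes (`Γ_c`).

## Worked example

Three vertices labeled `ACGT`, `GG`, `TTT` with edges
`v1→v2`, `v2→v3`, `v3→v2` (a two-vertex cycle), and four anchors tiling
a 13 bp query across the walk `v1·v2·v3·v2`:

```sh
python examples/02_chain_anchors.py
```

```
per-anchor optimal scores C[j]: [3, 4, 6, 7]
best score: 7
best chain (anchor indices): [0, 1, 2, 3]
vertices visited: ['v1', 'v2', 'v3', 'v2']
chaining passes: gamma_c = 1 (cyclic component: may exceed 1)
```

The best chain scores `3+2+3+2` anchor weight minus three query gaps of
1 and zero graph gaps = 7, and **visits `v2` twice** — expressible only
because same-vertex precedence is admitted on a proper cycle.

`examples/04_worst_case_convergence.py` shows the adversarial two-vertex
cycle with 8 anchors where the score front advances one anchor per pass:

```
passes executed: 5 (expected N/2 + 1 = 5)
  after pass 1: max C = 3496  (4.994 anchor weights)
  after pass 2: max C = 4198  (5.997 anchor weights)
  after pass 3: max C = 4900  (7.000 anchor weights)
  after pass 4: max C = 5600  (8.000 anchor weights)
  after pass 5: max C = 5600  (8.000 anchor weights)
```

The same workflow is available from the shell:

```sh
panchain simulate --vertices 10 --back-edges 2 --true 4 --noise 4 --seed 3 -o demo
panchain preprocess -g demo.gfa -o demo.index.json
panchain stats -i demo.index.json
panchain chain -i demo.index.json -a demo.anchors.tsv -o demo.chains.tsv --oracle
panchain verify -i demo.index.json -g demo.gfa
```

`--oracle` cross-checks every score against the quadratic DP and fails
loudly on any mismatch.

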