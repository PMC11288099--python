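# Methods

This note documents the model implemented by `panchain`, the numerical
and scheduling choices that were genuinely open, what the synthetic
generators do and do not emulate, and the package's known limitations.

## Graph model and distances

A pangenome graph is a directed graph whose vertices carry non-empty
labels over `{A,C,G,T}`; an edge `(v, u)` has length `|σ(v)|`, so a walk
spells the concatenation of the labels of the vertices it leaves.
Cycles and self-loops are permitted.  `D(v1, v2)` is the shortest-path
distance under these edge lengths (`0` on the diagonal, infinite when
unreachable), and `D°(v)` the length of the shortest proper cycle
through `v`.

Infinite distances are represented by `math.inf` alongside exact Python
integers.  Finite arithmetic therefore never loses precision, additions
involving the infinity saturate naturally, and no sentinel bookkeeping
is needed; serialization maps the infinity to JSON `null`.

## Preprocessing pipeline

Each weakly connected component is processed independently (components
cannot interact through either distances or chains).

1. **DAG-ification.**  Strongly connected components are found first;
   inside each SCC a depth-first search starting from the smallest
   vertex id, visiting sorted adjacency, removes every edge that points
   to a vertex on the current DFS stack.  Every cycle lies inside one
   SCC and contains a back edge of any DFS of that SCC, so the result is
   acyclic; edges between SCCs are never touched, so weak components are
   preserved.  The start-vertex and adjacency ordering are fixed purely
   for reproducibility — any DFS would be equally valid but could yield
   a different (equally valid) cover.
2. **Minimum path cover of the DAG** via minimum flow: each vertex
   becomes an arc `v⁻→v⁺` with demand 1 inside a split-vertex network
   with a global source and sink; a feasible flow of one unit per vertex
   is reduced by a max-flow from sink to source on the residual network,
   and the final flow decomposes greedily (smallest-successor first)
   into source-to-sink paths whose demand arcs spell the cover paths.
   Backward residual arcs are routed through private intermediate nodes
   so that the two opposite arcs a self-loop induces cannot alias each
   other's residual capacity.
3. **Lower bound.**  The same minimum-flow value computed on the
   *cyclic* component is a lower bound on any path cover's size (any
   cover is a feasible flow).  On DAGs the heuristic cover is provably
   minimum, so bound and cover size coincide.  Note that on cyclic
   components the minimum flow may satisfy demands by circulation alone
   (a lone self-loop vertex has bound 0), which keeps it a valid, if
   occasionally slack, certificate.
4. **Rank** is a topological order of the derived DAG (Kahn's algorithm,
   ties by vertex id).  Cover paths follow DAG edges, so ranks strictly
   increase along every path — the property the chaining sweep needs.
5. **last2reach** by label propagation: `L2R(v, i)` starts at `rank(v)`
   for `v` on `P_i`, and full sweeps in rank order take maxima over
   in-neighbors.  Any vertex of `P_i` reaching an in-neighbor of `v`
   also reaches `v`, and ranks grow along the path, so the running
   maximum converges to the true last reaching vertex within `|V|`
   value-changing sweeps (`Γ_l`).
6. **Distances from last2reach** by restricted relaxation: every vertex
   `w` on a shortest path from `t = last2reach(v, i)` to `v` satisfies
   `last2reach(w, i) = t` (a later path vertex reaching `w` would reach
   `v`, contradicting maximality of `t`), so Bellman–Ford sweeps that
   relax only edges whose endpoints share the l2r entry converge to the
   exact distance (`Γ_d` value-changing sweeps).  The exactness of this
   reconstruction is arbitrated by a Dijkstra oracle in the test suite,
   which is the authority.
7. **dist2begin** is a prefix sum of label lengths along each cover
   path; **`D°_P(v)`** is `min over out-neighbors u of |σ(v)| +
   D_P(u, v)`, finite exactly on vertices of proper cycles.

`D_P(v1, v2)` itself follows the cover path from `v1` to `α` — the
target if it sits on the path at or after `v1`, otherwise
`last2reach(v2, i)` provided that vertex sits at or after `v1` — and
appends the tabulated shortest path.  `D_P(v, v) = 0` by convention (the
pairwise formula is silent on the diagonal; cycle lengths are only ever
obtained through `D°_P`), and `D_P ≥ D` always, with equal finiteness.

## Chaining schedule

Scores are initialized to anchor weights and never decrease.  Each pass
rebuilds one range-max tree per cover path (keys: anchor query ends,
values: `−∞`) and executes a fixed task array sorted by
`(rank, stage, position, kind)` with stages *interleaved* <
*after-vertex* < *cycle* and, at equal positions, queries before updates
(so a same-vertex predecessor is visible only when its end lies strictly
before the successor's start).  The stored value for anchor `i` on
vertex `w` in tree `T_p` is `C[i] + i.d + i.y + dist2begin(w, p)`; a
query for anchor `j` via `(p, α)` forms
`RMQ + weight(j) + 2 − j.c − j.x − dist2begin(α, p) − D(α, j.v)`, which
algebraically equals `C[i] + weight(j) − gap_Q − gap_G`.  Candidates
from combinations whose implied walk is longer than the prescribed one
are strictly dominated, never overshoot, and the prescribed combination
is always scheduled, so the fixpoint equals the exact optimum of the
path-cover model — a fact the quadratic reference DP re-checks on every
tested instance rather than being trusted from the algebra.

Genuinely open choices, resolved as follows:

* **Cycle stage.**  All anchors of a cyclic vertex enter a per-vertex
  tree (keyed without the path terms), are processed in start-position
  order, and improvements are written back immediately to both the
  cycle tree and the path trees, so gains cascade within the stage;
  gains this ordering misses are picked up next pass.  Any consistent
  schedule converges to the same fixpoint; this one is deterministic
  and fast on the adversarial instance.
* **Iteration counting.**  `Γ_l`, `Γ_d` and `Γ_c` count value-changing
  passes; the final confirming pass is not counted, except that `Γ_c`
  is at least 1 because one pass must always run.  `n_passes`
  additionally includes the confirming pass.  On the adversarial
  two-vertex-cycle instance with `N` anchors the sweep executes
  `N/2 + 1` passes in total (`N/2` of them changing): the pass-1
  maximum is `N/2 + 1` anchor weights and each later pass adds exactly
  one more.
* **Convergence guard.**  A hard cap of `N` changing passes (per
  component, overridable) plus a warning guards pathological inputs;
  results are flagged unconverged and traceback then refuses to run.
* **Determinism.**  Range-max ties prefer the smallest anchor index;
  candidates must *strictly* improve a score to be taken; all weights
  and coordinates use exact integer arithmetic when inputs are
  integral.

Traceback follows parent pointers and re-scores the chain with the gap
functions; at a fixpoint the recomputed score provably equals `C[j*]`,
and the check is enforced at runtime.

## Synthetic data

`random_cyclic_graph` draws a DAG backbone (`v1→v2→…`, keeping one weak
component) with independent extra forward edges at a configurable
density, plus a requested number of strictly rank-decreasing back edges
that create cycles — the topology inversion/duplication variants induce
— with labels of 1–8 bp by default.  Defaults (20 vertices, density 0.1,
3 back edges, 8 true / 12 decoy anchors) keep instances small enough
that every quantity is verifiable against quadratic/cubic brute force;
the acceptance suite samples 2–30 vertices, ≤ 60 edges, 0–6 back edges
and ≤ 40 anchors.

`plant_chain_anchors` samples a random walk (which may loop through
cycles), spells it as the query, and plants full-label anchors on a
contiguous block of walk steps — a run of perfect seed matches, giving
zero query gaps inside the planted chain — before adding random decoys
that need not match the query text.  What this does *not* emulate:
sequencing errors, minimizer sampling and seed filtering, anchors
spanning vertex boundaries, biological variant structure, or realistic
genome-scale label lengths.  Passing tests therefore certify the
*chaining algorithm and its tables*, not end-to-end alignment accuracy
on real pangenomes.  Note the path-cover distance may over-estimate a
walk edge badly on these random graphs (their covers do not track the
walk the way genome-backbone covers do), so the optimal chain sometimes
keeps only a planted sub-chain; the planted score remains a certified
lower bound on the optimum in every case.

`worst_case_instance` is the adversarial convergence construction: two
single-character vertices in a cycle, anchors alternating between them
with adjacent unit query intervals, all weights equal to 100× the
largest pairwise gap so gap terms perturb the trajectory by under 1% of
a weight.

`kmer_seed` enumerates all exact k-mer matches between the query and
single vertex labels — a transparent stand-in for a minimizer seeder,
quadratic in sequence length by design.

## Limitations

* Anchors are confined to a single vertex; no base-level extension,
  mapping quality, multiple co-optimal chains, or overlap handling.
* The path cover is heuristic on cyclic graphs (exact minimum cover is
  NP-hard); different deterministic DFS choices could give different,
  equally valid covers and hence different `|P|` and `D_P`.
* GFA support covers v1 S/L lines with `0M` overlaps only; W/P lines
  and rGFA coordinates are out of scope.  `-` orientations require the
  reverse-complement augmented index.
* Brute-force oracles guard at 200 vertices / 500 anchors; the sparse
  path is not capped but has only been exercised at desk scales.
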