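"""Build a small cyclic pangenome graph and inspect its chaining index.

The graph has three labeled vertices with a two-vertex cycle
(v1 -> v2 <-> v3), the kind of structure an inversion or duplication
variant creates.  Preprocessing removes one back edge, covers the
derived DAG with a single path, and tabulates reachability and
distances relative to that cover.
"""

from panchain import PangenomeGraph, build_index

g = PangenomeGraph()
g.add_vertex("v1", "ACGT")
g.add_vertex("v2", "GG")
g.add_vertex("v3", "TTT")
g.add_edge("v1", "v2")
g.add_edge("v2", "v3")
g.add_edge("v3", "v2")

index = build_index(g)
comp = index.components[0]

print("cover paths:      ", comp.cover.paths)
print("removed back edges:", sorted(comp.removed_edges))
print("cover size lower bound (min flow):", comp.lower_bound)
print("rank:             ", comp.rank)
print("last2reach(v2, path 0):", comp.last2reach_vertex("v2", 0),
      "at distance", comp.d_l2r["v2"][0])
print("dist_pc(v3 -> v2):", comp.dist_pc("v3", "v2"),
      "(v3 reaches v2 through the back edge)")
print("dist_pc(v2 -> v1):", comp.dist_pc("v2", "v1"), "(unreachable)")
print("cycle distance at v2:", comp.cyc["v2"],
      "(shortest closed walk: |GG| + |TTT| = 5)")
print("iterations: gamma_l =", comp.gamma_l, ", gamma_d =", comp.gamma_d)
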