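"""Chain four anchors whose best chain loops through a cycle.

The anchors tile a query of 13 bp across the graph walk
v1 . v2 . v3 . v2 -- the chain must visit v2 twice, which is only
expressible because the precedence relation admits same-vertex pairs on
a proper cycle.  The optimal score is 3+2+3+2 anchor weight minus three
query gaps of 1 and zero graph gaps = 7.
"""

from panchain import Anchor, AnchorSet, PangenomeGraph, build_index, chain

g = PangenomeGraph()
g.add_vertex("v1", "ACGT")
g.add_vertex("v2", "GG")
g.add_vertex("v3", "TTT")
g.add_edge("v1", "v2")
g.add_edge("v2", "v3")
g.add_edge("v3", "v2")
index = build_index(g)

anchors = AnchorSet([
    Anchor("v1", 2, 4, 1, 3),    # CGT  matches Q[1..3]
    Anchor("v2", 1, 2, 5, 6),    # GG   matches Q[5..6]
    Anchor("v3", 1, 3, 8, 10),   # TTT  matches Q[8..10]
    Anchor("v2", 1, 2, 12, 13),  # GG again: the chain revisits v2
])

result = chain(anchors, index)
print("per-anchor optimal scores C[j]:", result.scores)
print("best score:", result.best_score)
print("best chain (anchor indices):", result.best_chain)
print("vertices visited:", [anchors[j].vertex for j in result.best_chain])
print("chaining passes: gamma_c =", result.gamma_c,
      "(cyclic component: may exceed 1)")
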