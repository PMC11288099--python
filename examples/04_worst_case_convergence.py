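"""Watch the iterative algorithm crawl on its worst-case input.

Two vertices forming a cycle, eight equal-weight anchors alternating
between them with adjacent unit query intervals: every anchor precedes
the next, but information can only flow one chain link per pass, so the
sweep needs N/2 + 1 passes.  The maximum of the score array reaches
N/2 + 1 anchor weights after the first pass and then grows by exactly
one anchor weight per pass (up to the small subtracted gap terms).
"""

from panchain import build_index, chain
from panchain.synthetic import worst_case_instance

N = 8
g, anchors = worst_case_instance(N)
index = build_index(g)
w = anchors[0].weight
print(f"graph: v1 <-> v2; {N} anchors of weight {w}")
print("cover:", index.components[0].cover.paths)

result = chain(anchors, index)
history = result.per_component[0][2]
print(f"passes executed: {result.n_passes} (expected N/2 + 1 = {N // 2 + 1})")
for p, m in enumerate(history, start=1):
    print(f"  after pass {p}: max C = {m}  ({m / w:.3f} anchor weights)")
print("best chain length:", len(result.best_chain), "(uses every anchor)")
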