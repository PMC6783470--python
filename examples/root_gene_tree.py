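"""Root an unrooted gene tree by minimal ancestor deviation (MAD).

MAD needs no outgroup: it places the root where the molecular-clock
expectation — every leaf pair's ancestor equidistant from both leaves —
is violated least, measured as the RMS relative deviation over all pairs.
"""

from thermoasr import mad_root, parse_newick

tree = parse_newick("((A:0.9,B:0.15):0.45,(C:0.7,(D:0.2,E:1.3):0.35):0.25,F:0.8);")
rooted, candidates, ambiguity = mad_root(tree)

best = candidates[0]
print(f"{len(candidates)} branches evaluated")
print(f"best root: branch {best.branch_id} (above node {best.child_label or '<internal>'}), "
      f"{best.x:.4f} substitutions/site from its parent end")
print(f"deviation score: {best.score:.4f} (0 would be perfectly clock-like)")
print(f"ambiguity index: {ambiguity:.4f} (best/second-best score; "
      f"values near 1 mean the placement is ambiguous)")
print()
print("rooted tree:", rooted.newick())
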