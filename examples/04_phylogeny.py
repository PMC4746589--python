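"""NJ tree with bootstrap supports, plus DAM calling by clade anchoring.

An alignment is evolved along a known tree with a DAM subclade inside the
MIKC^C subfamily; NJ + 200 column-resampling replicates rebuild it, and
queries are labeled by the smallest label-pure reference subtree around
them.
"""

import numpy as np

from madskit import phylo, simulate

dam = "(PDAM1:0.02,(Q1:0.02,(Q2:0.02,(Q3:0.02,PDAM2:0.02):0.02):0.02):0.02)"
nwk = (f"((REFMIKC1:0.05,({dam}:0.1,REFMIKC2:0.05):0.05):0.3,"
       f"(REFMA1:0.05,(MAQ1:0.05,REFMA2:0.05):0.05):0.3);")
rng = np.random.default_rng(0)
alignment = simulate.gen_alignment_on_tree(nwk, simulate._random_protein(rng, 300), seed=1, rate=0.5)

supported = phylo.bootstrap_support(alignment, n_reps=200, seed=2)
print("tree with supports:", supported.to_newick()[:120], "...")
print("internal-edge supports:",
      sorted(round(s) for s in supported.supports.values()))

refs = {"REFMIKC1": "MIKCc", "REFMIKC2": "MIKCc", "PDAM1": "MIKCc",
        "PDAM2": "MIKCc", "REFMA1": "Malpha", "REFMA2": "Malpha"}
anchors = {"PDAM1": "DAM", "PDAM2": "DAM"}
for call in phylo.assign_clades(supported, refs, anchors):
    if call.taxon.startswith(("Q", "MAQ")):
        print(f"  {call.taxon}: subfamily={call.label}, functional={call.functional}")
# Q1-Q3 sit in the peach-DAM-anchored subclade and are called DAM; MAQ1
# clades with the M-alpha references and gets no functional call.
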