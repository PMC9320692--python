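"""The borderline-discontinuity rule in action.

A tight clade whose lowest intra-clade ANIb (94.2%) sits just under the 95%
species threshold, but whose nearest outside genome is far below (92%), is
kept as one species by the discontinuity rule; with the rule disabled the
clade shatters into singletons.
"""

import numpy as np
import pandas as pd

from genotax import DelineationConfig, delineate
from genotax.ani import AniMatrix
from genotax.phylogeny import PhyloTree, read_newick

tree = PhyloTree(read_newick("(((P1:1,P2:1):1,P3:1):1,(Q1:1,Q2:1):1);"))
names = ["P1", "P2", "P3", "Q1", "Q2"]
directed = pd.DataFrame(np.nan, index=names, columns=names)
np.fill_diagonal(directed.values, 100.0)
values = {("P1", "P2"): 96.0, ("P1", "P3"): 94.2, ("P2", "P3"): 95.1,
          ("Q1", "Q2"): 97.0}
for p in ("P1", "P2", "P3"):
    for q in ("Q1", "Q2"):
        values[(p, q)] = 92.0
for (a, b), v in values.items():
    directed.loc[a, b] = directed.loc[b, a] = v
ani = AniMatrix(names, directed, {})

for label, cfg in [("rescue enabled (default)", DelineationConfig()),
                   ("rescue disabled", DelineationConfig(use_rescue=False))]:
    part = delineate(tree, ani, cfg)
    print(f"{label}: {part.n_clusters()} species -> "
          + "; ".join(",".join(c) for c in part.clusters()))
    for line in part.log:
        if "borderline" in line:
            print("   ", line)
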