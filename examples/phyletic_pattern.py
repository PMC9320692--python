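"""Gene-content (phyletic) clustering of simulated genomes.

The Jaccard similarity of presence/absence profiles clusters strains of the
same species together; the UPGMA dendrogram and a NEXUS export for splits-
network viewers are printed.
"""

from genotax import SimConfig, simulate
from genotax.phyletic import export_splits_distances, similarity_matrix, upgma

config = SimConfig(seed=9, n_species=3, strains_per_species=2,
                   n_genes=80, gene_len=300, gene_loss_rate=3.0, gene_gain_rate=2.0)
_, _, _, truth = simulate(config)

sim = similarity_matrix(truth.presence)
print("pairwise Jaccard similarity (gene content):")
print(sim.round(3).to_string())

dendro = upgma(1.0 - sim)
print("\nUPGMA dendrogram (heights = 1 - mean Jaccard, halved):")
print(dendro.newick())
print("\nfirst lines of the NEXUS distance export for SplitsTree:")
print("\n".join(export_splits_distances(1.0 - sim).splitlines()[:8]))
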