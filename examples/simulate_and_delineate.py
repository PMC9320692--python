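"""Simulate a small clade and delineate its phylogenomic species.

Builds a 3-species x 2-strain genome set with known truth, runs orthology,
the core-genome tree and the ANIb matrix, applies the 95%-ANI + monophyly
rule, and compares the result against the true species partition.
"""

from genotax import (SimConfig, anib_matrix, compare_partitions, delineate,
                     extract_genes, simulate)
from genotax.orthology import core_genes, ortholog_table
from genotax.phylogeny import align_family, bootstrap_support, concatenate

config = SimConfig(seed=42, n_species=3, strains_per_species=2,
                   n_genes=60, gene_len=450)
tree, genomes, annotations, truth = simulate(config)
print(f"simulated {len(genomes)} genomes, ~{genomes[0].length / 1000:.0f} kb each")

proteins = [p for g in genomes for p in extract_genes(g, annotations[g.genome_id])]
table, _ = ortholog_table(proteins)
core = core_genes(table)
print(f"{len(table.groups)} ortholog groups, {len(core)} universal single-copy (core)")

by_gene = {p.gene_id: p for p in proteins}
blocks = {gid: align_family({by_gene[m].genome_id: by_gene[m].protein for m in members})
          for gid, members in zip(table.pattern.columns, table.groups)
          if gid in set(core)}
aln = concatenate(blocks)
point, support = bootstrap_support(aln, replicates=100, seed=42)
print(f"core alignment: {aln.n_columns} aa columns; "
      f"min bootstrap support {min(support.values()):.0f}%")

ani = anib_matrix(genomes)
partition = delineate(point, ani)
for label in partition.labels:
    e = partition.evidence[label]
    intra = "-" if e.min_intra_ani is None else f"{e.min_intra_ani:.1f}"
    print(f"  {label}: {','.join(e.members)}  min intra ANI {intra}")

report = compare_partitions(partition, truth.partition)
print(f"Rand index vs truth: {report.rand_index:.2f} "
      "(1.0 = the true species partition was recovered exactly)")
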