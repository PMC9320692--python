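"""Shared fixtures.

``default_run`` executes the whole pipeline once per session on the default
simulated study (3 species x 4 strains, within-divergence 0.01, between
0.10, fixed seed) and exposes every intermediate; the expensive stages run
exactly once.  ``small_sim`` is a light 6-genome set for per-module tests.
"""

from __future__ import annotations

import pytest

from genotax.config import SimConfig
from genotax.genome_io import extract_genes
from genotax.orthology import core_genes, ortholog_table
from genotax.phylogeny import PhyloTree, align_family, bootstrap_support, concatenate, read_newick
from genotax.ani import anib_matrix
from genotax.delineation import delineate
from genotax.simulate import simulate

DEFAULT_SEED = 7


def run_study(sim_config: SimConfig) -> dict:
    """Simulate and run every pipeline stage, returning all intermediates."""
    tree, genomes, annotations, truth = simulate(sim_config)
    proteins = []
    for g in genomes:
        proteins.extend(extract_genes(g, annotations[g.genome_id]))
    table, hits = ortholog_table(proteins)
    core = core_genes(table)
    by_gene = {p.gene_id: p for p in proteins}
    blocks = {}
    for gid, members in zip(table.pattern.columns, table.groups):
        if gid in set(core):
            blocks[gid] = align_family(
                {by_gene[m].genome_id: by_gene[m].protein for m in members})
    aln = concatenate(blocks, sorted(g.genome_id for g in genomes))
    point, support = bootstrap_support(aln, replicates=100, seed=sim_config.seed)
    ani = anib_matrix(genomes)
    partition = delineate(point, ani)
    return {
        "config": sim_config,
        "sim_tree": tree,
        "genomes": genomes,
        "annotations": annotations,
        "truth": truth,
        "proteins": proteins,
        "table": table,
        "hits": hits,
        "core": core,
        "alignment": aln,
        "tree": point,
        "support": support,
        "ani": ani,
        "partition": partition,
        "true_tree": PhyloTree(read_newick(truth.tree_newick)),
    }


@pytest.fixture(scope="session")
def default_run() -> dict:
    return run_study(SimConfig(seed=DEFAULT_SEED))


@pytest.fixture(scope="session")
def small_sim() -> dict:
    cfg = SimConfig(seed=11, n_species=3, strains_per_species=2,
                    n_genes=40, gene_len=450)
    tree, genomes, annotations, truth = simulate(cfg)
    proteins = []
    for g in genomes:
        proteins.extend(extract_genes(g, annotations[g.genome_id]))
    table, hits = ortholog_table(proteins)
    return {"config": cfg, "sim_tree": tree, "genomes": genomes,
            "annotations": annotations, "truth": truth, "proteins": proteins,
            "table": table, "hits": hits}
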