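import itertools
import math

import dendropy
import numpy as np
import pytest
from skbio import DistanceMatrix

from genotax.config import PhylogenyConfig
from genotax.phylogeny import (CoreAlignment, PhyloTree, align_family,
                               bootstrap_support, concatenate, distance_matrix,
                               infer_tree, nj_tree, read_newick)


def aln_from_rows(rows: dict[str, str]) -> CoreAlignment:
    genomes = list(rows)
    matrix = np.array([np.frombuffer(rows[g].encode(), dtype=np.uint8)
                       for g in genomes])
    width = matrix.shape[1]
    return CoreAlignment(genomes, matrix, [("blk", 0, width)])


class TestAlignFamily:
    def test_identical_sequences_gap_free(self):
        block = align_family({"a": "MKVLYAADKRW", "b": "MKVLYAADKRW"})
        assert block["a"] == block["b"] == "MKVLYAADKRW"

    def test_internal_deletion_gets_gap(self):
        block = align_family({"x": "MKVLYAADKRW", "y": "MKVLADKRW"})
        assert block["y"].count("-") == 2
        assert block["x"] == "MKVLYAADKRW"

    def test_column_count_at_least_longest_input(self):
        seqs = {"a": "MKVLYAADKRW", "b": "MKVL", "c": "MKVLYAADKRWEE"}
        block = align_family(seqs)
        width = len(next(iter(block.values())))
        assert width >= max(len(s) for s in seqs.values())
        assert len({len(s) for s in block.values()}) == 1

    def test_single_sequence_unchanged(self):
        assert align_family({"a": "MKV"}) == {"a": "MKV"}


class TestConcatenate:
    def test_widths_and_partitions(self):
        blocks = {"g1": {"a": "MKVLY", "b": "MKVLY"},
                  "g2": {"a": "AADKRWE", "b": "AADKRWE"}}
        aln = concatenate(blocks)
        assert aln.n_columns == 12
        assert aln.partitions == [("g1", 0, 5), ("g2", 5, 12)]

    def test_row_order_independent(self):
        blocks = {"g1": {"a": "MKVLY", "b": "MAVLY"}}
        a1 = concatenate(blocks, ["a", "b"])
        a2 = concatenate(blocks, ["b", "a"])
        assert a1.row("a") == a2.row("a") and a1.row("b") == a2.row("b")

    def test_missing_genome_named_in_error(self):
        with pytest.raises(ValueError, match="g1"):
            concatenate({"g1": {"a": "MK"}}, ["a", "b"])

    def test_width_equals_sum_of_block_widths(self, small_sim):
        from genotax.orthology import core_genes
        table = small_sim["table"]
        by_gene = {p.gene_id: p for p in small_sim["proteins"]}
        blocks = {}
        for gid, members in zip(table.pattern.columns, table.groups):
            if gid in set(core_genes(table)):
                blocks[gid] = align_family(
                    {by_gene[m].genome_id: by_gene[m].protein for m in members})
        aln = concatenate(blocks)
        assert aln.n_columns == sum(
            len(next(iter(b.values()))) for b in blocks.values())


class TestDistanceMatrix:
    def test_identical_rows_zero(self):
        dm = distance_matrix(aln_from_rows({"a": "MKVLY", "b": "MKVLY"}))
        assert dm["a", "b"] == 0.0

    def test_poisson_correction_closed_form(self):
        # 1 mismatch in 10 comparable columns: d = -ln(0.9)
        dm = distance_matrix(aln_from_rows({"a": "MKVLYAADKR", "b": "MKVLYAADKW"}))
        assert dm["a", "b"] == pytest.approx(-math.log(0.9), abs=1e-10)
        assert dm["a", "b"] == pytest.approx(0.10536, abs=1e-5)

    def test_gap_columns_pairwise_deleted(self):
        dm = distance_matrix(aln_from_rows({"a": "MKVLY-ADKR", "b": "MKVLYAADKW"}))
        assert dm["a", "b"] == pytest.approx(-math.log(1 - 1 / 9), abs=1e-10)

    def test_no_comparable_columns_is_error(self):
        with pytest.raises(ValueError, match="comparable"):
            distance_matrix(aln_from_rows({"a": "MK--", "b": "--VL"}))


class TestInferTree:
    def test_nj_recovers_additive_quartet(self):
        d = np.array([[0, 2, 7, 7], [2, 0, 7, 7], [7, 7, 0, 2], [7, 7, 2, 0]],
                     dtype=float)
        tree = nj_tree(DistanceMatrix(d, ids=list("ABCD")))
        # the generating quartet beats the two alternatives
        assert tree.is_monophyletic({"A", "B"})
        assert not tree.is_monophyletic({"A", "C"})
        assert not tree.is_monophyletic({"A", "D"})

    def test_three_taxa_closed_form_branch_lengths(self):
        d = {"ab": 0.3, "ac": 0.5, "bc": 0.6}
        m = np.array([[0, d["ab"], d["ac"]],
                      [d["ab"], 0, d["bc"]],
                      [d["ac"], d["bc"], 0]])
        tree = nj_tree(DistanceMatrix(m, ids=list("abc")))
        expect = {"a": (d["ab"] + d["ac"] - d["bc"]) / 2,
                  "b": (d["ab"] + d["bc"] - d["ac"]) / 2,
                  "c": (d["ac"] + d["bc"] - d["ab"]) / 2}
        for tip in tree.tree.tips():
            assert tip.length == pytest.approx(expect[tip.name], abs=1e-10)

    def test_ml_poisson_recovers_strong_signal_topology(self, small_sim):
        from genotax.orthology import core_genes
        table = small_sim["table"]
        by_gene = {p.gene_id: p for p in small_sim["proteins"]}
        core = set(core_genes(table))
        blocks = {gid: align_family({by_gene[m].genome_id: by_gene[m].protein
                                     for m in members})
                  for gid, members in zip(table.pattern.columns, table.groups)
                  if gid in core}
        aln = concatenate(blocks)
        sub = CoreAlignment(aln.genomes[:5], aln.matrix[:5], aln.partitions)
        ml = infer_tree(sub, method="ml_poisson")
        nj = infer_tree(sub, method="nj")
        assert ml.rf_distance(nj) == 0

    def test_ml_taxa_limit(self):
        rows = {f"t{i}": "MKVLY" for i in range(20)}
        with pytest.raises(ValueError, match="nj"):
            infer_tree(aln_from_rows(rows), method="ml_poisson",
                       config=PhylogenyConfig(ml_max_taxa=15))

    def test_relabeling_invariance(self):
        rng = np.random.default_rng(5)
        d = rng.random((6, 6))
        d = (d + d.T) / 2
        np.fill_diagonal(d, 0)
        names = [f"t{i}" for i in range(6)]
        t1 = nj_tree(DistanceMatrix(d, ids=names))
        perm = [3, 1, 4, 0, 5, 2]
        t2 = nj_tree(DistanceMatrix(d[np.ix_(perm, perm)],
                                    ids=[names[i] for i in perm]))
        assert t1.rf_distance(t2) == 0

    def test_nj_on_ultrametric_matches_upgma(self):
        import pandas as pd
        from genotax.phyletic import upgma
        rng = np.random.default_rng(8)
        # build a random ultrametric matrix from a random dendrogram
        names = [f"t{i}" for i in range(7)]
        heights = {}
        clusters = [{n} for n in names]
        h = 0.0
        while len(clusters) > 1:
            h += float(rng.random()) + 0.05
            i, j = sorted(rng.choice(len(clusters), 2, replace=False))
            for a in clusters[i]:
                for b in clusters[j]:
                    heights[frozenset((a, b))] = h
            clusters[i] |= clusters.pop(j)
        d = pd.DataFrame(0.0, index=names, columns=names)
        for a, b in itertools.combinations(names, 2):
            d.loc[a, b] = d.loc[b, a] = 2 * heights[frozenset((a, b))]
        nj = nj_tree(DistanceMatrix(d.values, ids=names))
        dendro = upgma(d)
        up = PhyloTree(read_newick(dendro.newick()))
        assert nj.rf_distance(up) == 0


def dendropy_monophyly(newick: str, leafset: set[str]) -> bool:
    """Independent oracle: enumerate every edge's bipartition with dendropy."""
    tree = dendropy.Tree.get(data=newick, schema="newick",
                             preserve_underscores=True)
    taxa = {t.label for t in tree.taxon_namespace}
    if len(leafset) <= 1 or leafset == taxa:
        return True
    for edge in tree.preorder_edge_iter():
        if edge.head_node is tree.seed_node:
            continue
        side = {leaf.taxon.label for leaf in edge.head_node.leaf_iter()}
        if side == leafset or (taxa - side) == leafset:
            return True
    return False


class TestMonophyly:
    def test_textbook_quartet(self):
        t = PhyloTree(read_newick("((A:1,B:1):1,(C:1,D:1):1);"))
        assert t.is_monophyletic({"A", "B"})
        assert not t.is_monophyletic({"A", "C"})

    def test_trivial_sets(self):
        t = PhyloTree(read_newick("((A:1,B:1):1,(C:1,D:1):1);"))
        assert t.is_monophyletic({"A"})
        assert t.is_monophyletic({"A", "B", "C", "D"})

    def test_unknown_leaf_is_error(self):
        t = PhyloTree(read_newick("((A:1,B:1):1,(C:1,D:1):1);"))
        with pytest.raises(ValueError, match="unknown"):
            t.is_monophyletic({"A", "Z"})

    def test_agreement_with_edge_enumeration_on_random_trees(self):
        rng = np.random.default_rng(17)
        names = [f"L{i}" for i in range(8)]
        for rep in range(20):
            # random binary topology by sequential joining
            nodes = [f"{n}:1" for n in names]
            while len(nodes) > 1:
                i, j = sorted(rng.choice(len(nodes), 2, replace=False))
                b = nodes.pop(j)
                a = nodes.pop(i)
                nodes.append(f"({a},{b}):1")
            newick = nodes[0] + ";"
            tree = PhyloTree(read_newick(newick))
            for _ in range(25):
                k = int(rng.integers(1, 8))
                subset = set(rng.choice(names, size=k, replace=False))
                assert tree.is_monophyletic(subset) == \
                    dendropy_monophyly(newick, subset), (newick, subset)


class TestBootstrap:
    @pytest.fixture(scope="class")
    def signal_alignment(self, small_sim):
        from genotax.orthology import core_genes
        table = small_sim["table"]
        by_gene = {p.gene_id: p for p in small_sim["proteins"]}
        core = set(core_genes(table))
        blocks = {gid: align_family({by_gene[m].genome_id: by_gene[m].protein
                                     for m in members})
                  for gid, members in zip(table.pattern.columns, table.groups)
                  if gid in core}
        return concatenate(blocks)

    def test_strong_signal_full_support(self, signal_alignment):
        _, support = bootstrap_support(signal_alignment, replicates=100, seed=1)
        assert support and all(v == 100.0 for v in support.values())

    def test_fixed_seed_reproducible(self, signal_alignment):
        _, s1 = bootstrap_support(signal_alignment, replicates=25, seed=9)
        _, s2 = bootstrap_support(signal_alignment, replicates=25, seed=9)
        assert s1 == s2

    def test_single_replicate_support_binary(self, signal_alignment):
        _, support = bootstrap_support(signal_alignment, replicates=1, seed=2)
        assert set(support.values()) <= {0.0, 100.0}

    def test_replicate_count_validated(self, signal_alignment):
        with pytest.raises(ValueError):
            bootstrap_support(signal_alignment, replicates=0)
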