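import itertools

import networkx as nx
import numpy as np
import pytest

from genotax.config import OrthologyConfig
from genotax.genome_io import GeneRecord
from genotax.orthology import (Hit, all_vs_all, build_ortholog_groups, core_genes,
                               ortholog_table, reciprocal_best_hits)


def prot(gene_id, genome_id, seq):
    return GeneRecord(gene_id, genome_id, "c1", 0, 3 * len(seq) + 3, "+", seq)


RNG = np.random.default_rng(12)
AA = list("ACDEFGHIKLMNPQRSTVWY")


def random_protein(n=120):
    return "".join(RNG.choice(AA, size=n))


@pytest.fixture(scope="module")
def twin_proteomes():
    seqs = [random_protein() for _ in range(5)]
    a = [prot(f"a{i}", "A", s) for i, s in enumerate(seqs)]
    b = [prot(f"b{i}", "B", s) for i, s in enumerate(seqs)]
    return a, b


class TestAllVsAll:
    def test_identical_proteomes_hit_at_identity_100(self, twin_proteomes):
        a, b = twin_proteomes
        hits = all_vs_all(a + b, identity_min=70, evalue_max=0.01)
        own = {(h.query_gene, h.subject_gene) for h in hits}
        for i in range(5):
            assert (f"a{i}", f"b{i}") in own
        for h in hits:
            if h.query_gene.lstrip("ab") == h.subject_gene.lstrip("ab"):
                assert h.identity == 100.0

    def test_shuffled_decoy_has_no_hit_at_70(self):
        base = random_protein(150)
        decoy = "".join(RNG.permutation(list(base)))
        genes = [prot("x", "A", base), prot("y", "B", decoy)]
        cfg = OrthologyConfig(use_prefilter=False)
        hits = all_vs_all(genes, identity_min=70, evalue_max=10.0, config=cfg)
        assert hits == []

    def test_threshold_sweep_monotone(self, small_sim):
        pair = [p for p in small_sim["proteins"]
                if p.genome_id in ("sp1_st1", "sp2_st1")]
        counts = []
        for identity_min in (50, 60, 70, 80):
            hits = all_vs_all(pair, identity_min=identity_min, evalue_max=0.01)
            counts.append(len(hits))
        assert counts == sorted(counts, reverse=True)

    def test_empty_proteome_warned_not_fatal(self, caplog):
        genes = [prot("x", "A", random_protein()),
                 GeneRecord("y", "B", "c1", 0, 3, "+", "")]
        hits = all_vs_all(genes, identity_min=70, evalue_max=0.01)
        assert hits == []
        assert "empty proteome" in caplog.text


def brute_force_rbh(hits, ga, gb):
    """Independent RBH: exhaustive best-hit maps both ways."""
    def best(qg, sg):
        out = {}
        for h in hits:
            if h.query_genome == qg and h.subject_genome == sg:
                key = (h.score, h.identity, tuple(-ord(c) for c in h.subject_gene))
                if h.query_gene not in out or key > out[h.query_gene][0]:
                    out[h.query_gene] = (key, h.subject_gene)
        return {q: s for q, (_, s) in out.items()}

    f, r = best(ga, gb), best(gb, ga)
    return sorted((x, y) for x, y in f.items() if r.get(y) == x)


class TestReciprocalBestHits:
    def test_identical_proteomes_identity_mapping(self, twin_proteomes):
        a, b = twin_proteomes
        hits = all_vs_all(a + b, identity_min=70, evalue_max=0.01)
        pairs = reciprocal_best_hits(hits, "A", "B")
        assert pairs == [(f"a{i}", f"b{i}") for i in range(5)]

    def test_paralog_resolved_to_best_copy(self):
        def mk(q, s, qg, sg, score, ident):
            return Hit(q, s, qg, sg, ident, score, 1e-20, 100)
        hits = [mk("x", "y1", "A", "B", 500, 99), mk("y1", "x", "B", "A", 500, 99),
                mk("x", "y2", "A", "B", 480, 95), mk("y2", "x", "B", "A", 480, 95)]
        assert reciprocal_best_hits(hits, "A", "B") == [("x", "y1")]
        assert brute_force_rbh(hits, "A", "B") == [("x", "y1")]

    def test_asymmetric_best_hits_not_paired(self):
        def mk(q, s, qg, sg, score):
            return Hit(q, s, qg, sg, 90, score, 1e-20, 100)
        # x's best is y, but y's best is z
        hits = [mk("x", "y", "A", "B", 400), mk("y", "x", "B", "A", 300),
                mk("y", "z", "B", "A", 400), mk("z", "y", "A", "B", 400)]
        pairs = reciprocal_best_hits(hits, "A", "B")
        assert ("x", "y") not in pairs

    def test_symmetric_in_genome_order(self, small_sim):
        hits = [h for h in small_sim["hits"]
                if {h.query_genome, h.subject_genome} == {"sp1_st1", "sp1_st2"}]
        ab = reciprocal_best_hits(hits, "sp1_st1", "sp1_st2")
        ba = reciprocal_best_hits(hits, "sp1_st2", "sp1_st1")
        assert {tuple(sorted(p)) for p in ab} == {tuple(sorted(p)) for p in ba}

    def test_matches_brute_force_without_prefilter(self, small_sim):
        pair = [p for p in small_sim["proteins"]
                if p.genome_id in ("sp1_st1", "sp3_st1")]
        cfg = OrthologyConfig(use_prefilter=False)
        hits = all_vs_all(pair, config=cfg)
        assert reciprocal_best_hits(hits, "sp1_st1", "sp3_st1") == \
            brute_force_rbh(hits, "sp1_st1", "sp3_st1")


class TestOrthologGroups:
    def test_complete_triangle_gives_all_ones_pattern(self):
        seqs = [random_protein() for _ in range(4)]
        genes = [prot(f"{g}{i}", g, s)
                 for g in "ABC" for i, s in enumerate(seqs)]
        table, _ = ortholog_table(genes)
        assert len(table.groups) == 4
        assert (table.pattern.values == 1).all()

    def test_components_equal_networkx(self, small_sim):
        genomes = sorted({p.genome_id for p in small_sim["proteins"]})
        by_pair = {}
        for h in small_sim["hits"]:
            by_pair.setdefault(tuple(sorted((h.query_genome, h.subject_genome))), []).append(h)
        pairs = []
        for ga, gb in itertools.combinations(genomes, 2):
            pairs.extend(reciprocal_best_hits(by_pair.get((ga, gb), []), ga, gb))
        table = build_ortholog_groups(pairs, small_sim["proteins"])
        g = nx.Graph()
        g.add_nodes_from(p.gene_id for p in small_sim["proteins"])
        g.add_edges_from(pairs)
        expected = {frozenset(c) for c in nx.connected_components(g)}
        assert set(table.groups) == expected

    def test_simulated_loss_shows_in_pattern(self, small_sim):
        table = small_sim["truth"].presence
        inferred = small_sim["table"].pattern
        # families lost somewhere are absent exactly there in the inferred table
        fam_of_group = {}
        for gid, members in zip(small_sim["table"].pattern.columns,
                                small_sim["table"].groups):
            fams = {m.rsplit("|", 1)[0] for m in members}
            assert len(fams) == 1, "no simulated family may be cross-linked"
            fam_of_group[gid] = fams.pop()
        for gid, fam in fam_of_group.items():
            assert (inferred[gid] == table[fam].loc[inferred.index]).all()


class TestCoreGenes:
    def test_all_ones_single_copy_all_core(self):
        seqs = [random_protein() for _ in range(3)]
        genes = [prot(f"{g}{i}", g, s) for g in "AB" for i, s in enumerate(seqs)]
        table, _ = ortholog_table(genes)
        assert len(core_genes(table)) == 3

    def test_missing_in_one_genome_excluded(self):
        seqs = [random_protein() for _ in range(3)]
        genes = [prot(f"A{i}", "A", s) for i, s in enumerate(seqs)]
        genes += [prot(f"B{i}", "B", s) for i, s in enumerate(seqs[:2])]
        table, _ = ortholog_table(genes)
        assert len(core_genes(table)) == 2

    def test_core_equals_simulator_truth(self, small_sim):
        core = core_genes(small_sim["table"])
        fams = set()
        for gid, members in zip(small_sim["table"].pattern.columns,
                                small_sim["table"].groups):
            if gid in set(core):
                fams.add(next(iter(members)).rsplit("|", 1)[0])
        assert fams == set(small_sim["truth"].families_untouched_by_loss)

    def test_raising_identity_never_enlarges_core(self, small_sim):
        sizes = []
        for identity_min in (50, 70, 90):
            cfg = OrthologyConfig(identity_min=identity_min)
            table, _ = ortholog_table(small_sim["proteins"], cfg)
            try:
                sizes.append(len(core_genes(table)))
            except ValueError as exc:
                # an over-strict threshold empties the core with advice
                assert "lowering the identity threshold" in str(exc)
                sizes.append(0)
        assert sizes == sorted(sizes, reverse=True)
        assert sizes[0] > 0

    def test_empty_table_rejected(self):
        import pandas as pd
        from genotax.orthology import OrthologTable
        empty = OrthologTable([], pd.DataFrame(), pd.DataFrame(), 70, 0.01)
        with pytest.raises(ValueError):
            core_genes(empty)
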