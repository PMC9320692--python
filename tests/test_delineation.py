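import itertools

import numpy as np
import pandas as pd
import pytest

from genotax.ani import AniMatrix
from genotax.config import DelineationConfig
from genotax.delineation import (PgsPartition, compare_partitions, delineate,
                                 detect_synonyms)
from genotax.phylogeny import PhyloTree, read_newick


def matrix_from(values: dict[tuple[str, str], float], names: list[str]) -> AniMatrix:
    directed = pd.DataFrame(np.nan, index=names, columns=names)
    np.fill_diagonal(directed.values, 100.0)
    for (a, b), v in values.items():
        directed.loc[a, b] = directed.loc[b, a] = v
    return AniMatrix(names, directed, {})


@pytest.fixture()
def quartet():
    tree = PhyloTree(read_newick("((A:1,B:1):1,(C:1,D:1):1);"))
    ani = matrix_from({("A", "B"): 97, ("C", "D"): 98,
                       ("A", "C"): 85, ("A", "D"): 85,
                       ("B", "C"): 85, ("B", "D"): 85}, list("ABCD"))
    return tree, ani


class TestDelineate:
    def test_clear_cut_two_species(self, quartet):
        tree, ani = quartet
        part = delineate(tree, ani)
        assert part.clusters() == [["A", "B"], ["C", "D"]]
        for label in part.labels:
            assert part.evidence[label].monophyletic

    def test_borderline_discontinuity_keeps_single_cluster(self):
        # a tight clade just under the threshold, far from everything else
        tree = PhyloTree(read_newick("(((P1:1,P2:1):1,P3:1):1,(Q1:1,Q2:1):1);"))
        vals = {("P1", "P2"): 96.0, ("P1", "P3"): 94.2, ("P2", "P3"): 95.1,
                ("Q1", "Q2"): 97.0}
        for p in ("P1", "P2", "P3"):
            for q in ("Q1", "Q2"):
                vals[(p, q)] = 92.0
        ani = matrix_from(vals, ["P1", "P2", "P3", "Q1", "Q2"])
        part = delineate(tree, ani)
        assert ["P1", "P2", "P3"] in part.clusters()
        label = part.assignment["P1"]
        assert part.evidence[label].borderline
        assert part.evidence[label].rescued_by == "discontinuity"

    def test_borderline_clade_splits_without_rescue(self):
        tree = PhyloTree(read_newick("(((P1:1,P2:1):1,P3:1):1,(Q1:1,Q2:1):1);"))
        vals = {("P1", "P2"): 96.0, ("P1", "P3"): 94.2, ("P2", "P3"): 95.1,
                ("Q1", "Q2"): 97.0}
        for p in ("P1", "P2", "P3"):
            for q in ("Q1", "Q2"):
                vals[(p, q)] = 92.0
        ani = matrix_from(vals, ["P1", "P2", "P3", "Q1", "Q2"])
        part = delineate(tree, ani, DelineationConfig(use_rescue=False))
        assert ["P1", "P2", "P3"] not in part.clusters()
        assert ["P1", "P2"] in part.clusters()
        assert ["P3"] in part.clusters()

    def test_ddh_rescue_route(self):
        tree = PhyloTree(read_newick("(((P1:1,P2:1):1,P3:1):1,(Q1:1,Q2:1):1);"))
        vals = {("P1", "P2"): 96.0, ("P1", "P3"): 94.2, ("P2", "P3"): 95.1,
                ("Q1", "Q2"): 97.0}
        for p in ("P1", "P2", "P3"):
            for q in ("Q1", "Q2"):
                vals[(p, q)] = 93.5   # gap 0.7 < 2.0: discontinuity fails
        ani = matrix_from(vals, ["P1", "P2", "P3", "Q1", "Q2"])
        names = ["P1", "P2", "P3", "Q1", "Q2"]
        ddh = pd.DataFrame(30.0, index=names, columns=names)
        for a, b in itertools.combinations(("P1", "P2", "P3"), 2):
            ddh.loc[a, b] = ddh.loc[b, a] = 74.0
        part = delineate(tree, ani, ddh=ddh)
        assert ["P1", "P2", "P3"] in part.clusters()
        assert part.evidence[part.assignment["P1"]].rescued_by == "ddh"

    def test_failed_triple_decomposes_to_pair_plus_singleton(self):
        tree = PhyloTree(read_newick("(((A:1,B:1):1,C:1):1,(D:1,E:1):1);"))
        vals = {("A", "B"): 96, ("B", "C"): 96, ("A", "C"): 93, ("D", "E"): 98}
        for x in "ABC":
            for y in "DE":
                vals[(x, y)] = 85
        ani = matrix_from(vals, list("ABCDE"))
        part = delineate(tree, ani, DelineationConfig(use_rescue=False))
        assert ["A", "B"] in part.clusters()
        assert ["C"] in part.clusters()
        assert sorted(part.clusters()) == sorted(exhaustive_delineation(tree, ani, 95.0))

    def test_missing_ani_rejects_clade_with_explanation(self, quartet):
        tree, _ = quartet
        ani = matrix_from({("A", "B"): np.nan, ("C", "D"): 98,
                           ("A", "C"): 85, ("A", "D"): 85,
                           ("B", "C"): 85, ("B", "D"): 85}, list("ABCD"))
        part = delineate(tree, ani)
        assert ["A"] in part.clusters() and ["B"] in part.clusters()
        assert any("missing ANI" in line for line in part.log)

    def test_multi_member_clusters_always_monophyletic(self, default_run):
        part = default_run["partition"]
        tree = default_run["tree"]
        for label in part.labels:
            members = part.members(label)
            if len(members) > 1:
                assert tree.is_monophyletic(set(members))

    def test_threshold_monotone_refinement(self, default_run):
        tree, ani = default_run["tree"], default_run["ani"]
        previous = None
        for thr in (80.0, 90.0, 95.0, 99.0):
            part = delineate(tree, ani, DelineationConfig(ani_threshold=thr,
                                                          use_rescue=False))
            clusters = [set(c) for c in part.clusters()]
            if previous is not None:
                for c in clusters:
                    assert any(c <= p for p in previous), (thr, c)
            previous = clusters


def exhaustive_delineation(tree: PhyloTree, ani: AniMatrix, thr: float):
    """Independent oracle: scan every clade largest-first, accept on the
    plain min-intra-ANI rule, no rescue."""
    sym = ani.symmetric
    leaves = set(tree.leaf_names)
    taken: set[str] = set()
    accepted = []
    for clade in tree.clades():
        if len(clade) < 2 or clade & taken:
            continue
        pairs = list(itertools.combinations(sorted(clade), 2))
        vals = [sym.loc[a, b] for a, b in pairs]
        if any(pd.isna(v) for v in vals) or min(vals) < thr:
            continue
        accepted.append(sorted(clade))
        taken |= clade
    accepted += [[g] for g in sorted(leaves - taken)]
    labels = sorted(accepted, key=lambda c: (-len(c), c[0]))
    return sorted(labels, key=lambda c: c[0])


class TestComparePartitions:
    def test_identical_partitions(self):
        p = {"a": "1", "b": "1", "c": "2"}
        rep = compare_partitions(p, {"a": "x", "b": "x", "c": "y"})
        assert rep.rand_index == 1.0
        assert rep.splits == [] and rep.merges == []

    def test_split_reported_with_members(self):
        p1 = {"a": "1", "b": "1", "c": "1"}
        p2 = {"a": "x", "b": "x", "c": "y"}
        rep = compare_partitions(p1, p2)
        assert rep.splits == [("1", ["x", "y"])]

    def test_rand_index_equals_pair_counting(self):
        rng = np.random.default_rng(9)
        genomes = [f"g{i}" for i in range(12)]
        for _ in range(20):
            p1 = {g: f"c{rng.integers(4)}" for g in genomes}
            p2 = {g: f"d{rng.integers(3)}" for g in genomes}
            agree = 0
            pairs = list(itertools.combinations(genomes, 2))
            for a, b in pairs:
                same1 = p1[a] == p1[b]
                same2 = p2[a] == p2[b]
                agree += same1 == same2
            rep = compare_partitions(p1, p2)
            assert rep.rand_index == pytest.approx(agree / len(pairs))

    def test_disjoint_sets_rejected(self):
        with pytest.raises(ValueError):
            compare_partitions({"a": "1"}, {"b": "2"})

    def test_true_partition_recovered_on_simulated_data(self, default_run):
        rep = compare_partitions(default_run["partition"],
                                 default_run["truth"].partition)
        assert rep.rand_index == 1.0


class TestDetectSynonyms:
    def _partition(self, assignment):
        return PgsPartition(assignment, {label: None for label in set(assignment.values())})

    def test_two_names_in_one_pgs(self):
        part = self._partition({"t1": "pgs3", "t2": "pgs3", "t3": "pgs4"})
        groups = detect_synonyms(part, {"t1": "P. kunmingensis",
                                        "t2": "S. chloritidismutans"})
        assert groups == [["P. kunmingensis", "S. chloritidismutans"]]

    def test_no_multi_name_pgs_empty(self):
        part = self._partition({"t1": "pgs1", "t2": "pgs2"})
        assert detect_synonyms(part, {"t1": "A", "t2": "B"}) == []

    def test_three_names_single_group(self):
        part = self._partition({"t1": "pgs1", "t2": "pgs1", "t3": "pgs1"})
        groups = detect_synonyms(part, {"t1": "A", "t2": "B", "t3": "C"})
        assert groups == [["A", "B", "C"]]
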