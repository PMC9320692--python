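"""Phylogenomic species delineation.

A phylogenomic species (pgs) is a maximal clade of the core-genome tree
whose members all share genomic indices at or above the species thresholds:
ANIb >= 95% (or dDDH >= 70%).  Clades are scanned largest-first over the
bipartitions of the unrooted tree; accepted clades are disjoint by
construction; genomes in no accepted multi-member clade become singletons.

A clade whose minimum intra-clade ANI falls short of the threshold by at
most ``borderline_delta`` points can still be accepted ("rescued") when
either

* a clear discontinuity separates it from everything else — the highest ANI
  from any member to any non-member is at least ``discontinuity_gap`` points
  below the minimum intra-clade ANI — or
* every intra-clade pair reaches the dDDH threshold.

This borderline rule is load-bearing: a tight cluster sitting just under
the ANI cutoff but well separated from its neighbours is one species, not a
dust of singletons.  Every accept/reject decision is logged with evidence.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import pandas as pd
from sklearn.metrics import rand_score

from .ani import AniMatrix
from .config import DelineationConfig
from .phylogeny import PhyloTree


@dataclass
class ClusterEvidence:
    label: str
    members: list[str]
    min_intra_ani: float | None
    max_outside_ani: float | None
    monophyletic: bool
    borderline: bool
    rescued_by: str | None          # "discontinuity", "ddh" or None
    min_intra_ddh: float | None = None


@dataclass
class PgsPartition:
    """Assignment of genomes to phylogenomic species, with evidence."""

    assignment: dict[str, str]
    evidence: dict[str, ClusterEvidence]
    log: list[str] = field(default_factory=list)

    @property
    def labels(self) -> list[str]:
        return sorted(set(self.assignment.values()))

    def members(self, label: str) -> list[str]:
        return sorted(g for g, l in self.assignment.items() if l == label)

    def clusters(self) -> list[list[str]]:
        return [self.members(l) for l in self.labels]

    def n_clusters(self, include_singletons: bool = True) -> int:
        sizes = [len(self.members(l)) for l in self.labels]
        if include_singletons:
            return len(sizes)
        return sum(1 for s in sizes if s > 1)

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("genome_id\tpgs_label\n")
            for g in sorted(self.assignment):
                fh.write(f"{g}\t{self.assignment[g]}\n")

    def evidence_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("pgs_label\tn_members\tmin_intra_ani\tmax_outside_ani\t"
                     "monophyletic\tborderline\trescued_by\tmembers\n")
            for label in self.labels:
                e = self.evidence[label]
                fh.write("\t".join([
                    label, str(len(e.members)),
                    "" if e.min_intra_ani is None else f"{e.min_intra_ani:.2f}",
                    "" if e.max_outside_ani is None else f"{e.max_outside_ani:.2f}",
                    str(e.monophyletic), str(e.borderline),
                    e.rescued_by or "", ",".join(e.members)]) + "\n")


def _intra_stats(members: list[str], sym: pd.DataFrame) -> tuple[float | None, bool]:
    """(min intra ANI, all-defined flag) over unordered member pairs."""
    vals = []
    for a, b in itertools.combinations(members, 2):
        v = sym.loc[a, b]
        if pd.isna(v):
            return None, False
        vals.append(float(v))
    return (min(vals) if vals else None), True


def _max_outside(members: list[str], others: list[str], sym: pd.DataFrame) -> float | None:
    vals = [float(sym.loc[a, b]) for a in members for b in others
            if not pd.isna(sym.loc[a, b])]
    return max(vals) if vals else None


def delineate(
    tree: PhyloTree,
    ani: AniMatrix,
    config: DelineationConfig | None = None,
    ddh: pd.DataFrame | None = None,
    seed_labels: dict[str, str] | None = None,
) -> PgsPartition:
    """Partition genomes into phylogenomic species.

    ``ddh``: optional symmetric dDDH matrix used only for borderline rescue.
    ``seed_labels``: optional genome -> label map (e.g. reference strains);
    a cluster containing a seeded genome inherits its label, other clusters
    are numbered by decreasing size then lexicographic smallest member.
    """
    config = config or DelineationConfig()
    leaves = set(tree.leaf_names)
    if leaves != set(ani.genomes):
        raise ValueError("tree leaves and ANI matrix genomes must coincide")
    sym = ani.symmetric
    log: list[str] = []
    accepted: list[tuple[list[str], ClusterEvidence]] = []
    assigned: set[str] = set()

    for clade in tree.clades():
        if len(clade) < 2 or clade & assigned:
            continue
        members = sorted(clade)
        others = sorted(leaves - clade)
        min_intra, defined = _intra_stats(members, sym)
        if not defined:
            log.append(f"reject {members}: missing ANI values inside the clade")
            continue
        max_out = _max_outside(members, others, sym)
        borderline = False
        rescued_by = None
        if min_intra >= config.ani_threshold:
            ok = True
        elif (config.use_rescue
              and min_intra >= config.ani_threshold - config.borderline_delta):
            borderline = True
            gap_ok = (max_out is None
                      or max_out <= min_intra - config.discontinuity_gap)
            ddh_ok = False
            min_ddh = None
            if ddh is not None:
                dvals = [float(ddh.loc[a, b])
                         for a, b in itertools.combinations(members, 2)
                         if not pd.isna(ddh.loc[a, b])]
                if dvals and len(dvals) == math.comb(len(members), 2):
                    min_ddh = min(dvals)
                    ddh_ok = min_ddh >= config.ddh_threshold
            if gap_ok:
                rescued_by = "discontinuity"
            elif ddh_ok:
                rescued_by = "ddh"
            ok = rescued_by is not None
            if ok:
                log.append(f"accept {members}: borderline min intra ANI "
                           f"{min_intra:.2f} rescued by {rescued_by}")
        else:
            ok = False
        if ok:
            ev = ClusterEvidence("", members, min_intra, max_out, True,
                                 borderline, rescued_by)
            if borderline and ddh is not None:
                ev.min_intra_ddh = min_ddh
            accepted.append((members, ev))
            assigned |= set(members)
            if not borderline:
                log.append(f"accept {members}: min intra ANI {min_intra:.2f}")
        else:
            log.append(f"reject {members}: min intra ANI {min_intra:.2f} "
                       f"below threshold {config.ani_threshold}")

    for genome in sorted(leaves - assigned):
        ev = ClusterEvidence("", [genome], None,
                             _max_outside([genome], sorted(leaves - {genome}), sym),
                             True, False, None)
        accepted.append(([genome], ev))

    # stable numbering: seeded labels first, then size, then smallest member
    accepted.sort(key=lambda me: (-len(me[0]), me[0][0]))
    assignment: dict[str, str] = {}
    evidence: dict[str, ClusterEvidence] = {}
    counter = itertools.count(1)
    used: set[str] = set()
    for members, ev in accepted:
        label = None
        if seed_labels:
            seeded = sorted({seed_labels[g] for g in members if g in seed_labels})
            if seeded and seeded[0] not in used:
                label = seeded[0]
        if label is None:
            while (label := f"pgs{next(counter)}") in used:
                pass
        used.add(label)
        ev.label = label
        evidence[label] = ev
        for g in members:
            assignment[g] = label
    return PgsPartition(assignment, evidence, log)


@dataclass
class ConcordanceReport:
    rand_index: float
    splits: list[tuple[str, list[str]]]     # p1 label spread over >1 p2 labels
    merges: list[tuple[str, list[str]]]     # p2 label spread over >1 p1 labels
    n_genomes: int

    def to_text(self) -> str:
        lines = [f"Rand index: {self.rand_index:.4f} over {self.n_genomes} genomes"]
        for label, parts in self.splits:
            lines.append(f"split: {label} -> {', '.join(parts)}")
        for label, parts in self.merges:
            lines.append(f"merge: {label} <- {', '.join(parts)}")
        if not self.splits and not self.merges:
            lines.append("partitions are identical up to label names")
        return "\n".join(lines)


def compare_partitions(p1: dict[str, str] | PgsPartition,
                       p2: dict[str, str] | PgsPartition) -> ConcordanceReport:
    """Pairwise co-membership agreement between two labelings.

    Computed over the genomes present in both; reports the Rand index plus
    every label split one way or the other.
    """
    a1 = p1.assignment if isinstance(p1, PgsPartition) else dict(p1)
    a2 = p2.assignment if isinstance(p2, PgsPartition) else dict(p2)
    common = sorted(set(a1) & set(a2))
    if not common:
        raise ValueError("partitions share no genomes")
    l1 = [a1[g] for g in common]
    l2 = [a2[g] for g in common]
    ri = float(rand_score(l1, l2))
    splits = []
    for label in sorted(set(l1)):
        members = [g for g in common if a1[g] == label]
        targets = sorted({a2[g] for g in members})
        if len(targets) > 1:
            splits.append((label, targets))
    merges = []
    for label in sorted(set(l2)):
        members = [g for g in common if a2[g] == label]
        sources = sorted({a1[g] for g in members})
        if len(sources) > 1:
            merges.append((label, sources))
    return ConcordanceReport(ri, splits, merges, len(common))


def detect_synonyms(partition: PgsPartition,
                    type_strains: dict[str, str]) -> list[list[str]]:
    """Synonymy candidates: species names whose type/reference strains fall
    in the same phylogenomic species.

    ``type_strains`` maps genome_id -> species name.  Returns one sorted
    name group per pgs containing two or more distinct names.
    """
    groups = []
    for label in partition.labels:
        names = sorted({type_strains[g] for g in partition.members(label)
                        if g in type_strains})
        if len(names) >= 2:
            groups.append(names)
    return groups
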