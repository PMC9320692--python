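"""All-vs-all protein homology search, reciprocal-best-hit orthology, and
the core gene set / phyletic pattern.

Every protein is compared against the proteins of every other genome with a
local alignment (BLOSUM62, affine gaps) after a shared-k-mer prefilter.
Hits are kept at a configurable percent-identity floor (the study's working
value is 70%) and an e-value ceiling (0.01).  Orthologous genes are grouped
by best reciprocal hits: (x, y) is kept iff y is x's highest-scoring hit in
y's genome and vice versa; ortholog groups are the connected components of
the RBH graph across all genome pairs.

E-values use the classical extreme-value (Karlin-Altschul-style) form
E = K*m*n*exp(-lambda*S) with lambda and K fitted once per run on shuffled
decoy proteins, giving the same cutoff semantics as a database search
without claiming bit-compatibility with any particular engine.
"""

from __future__ import annotations

import logging
import math
from collections import Counter, defaultdict
from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices

from .config import OrthologyConfig
from .genome_io import GeneRecord

logger = logging.getLogger(__name__)


@dataclass
class Hit:
    query_gene: str
    subject_gene: str
    query_genome: str
    subject_genome: str
    identity: float      # percent identical over aligned columns (incl. internal gaps)
    score: float
    evalue: float
    aln_len: int


def _make_aligner(config: OrthologyConfig) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner(scoring=None)
    aligner.substitution_matrix = substitution_matrices.load(config.matrix)
    aligner.open_gap_score = config.gap_open
    aligner.extend_gap_score = config.gap_extend
    aligner.mode = "local"
    return aligner


class EvalueModel:
    """Gumbel-tail score statistics fitted on shuffled decoy alignments."""

    def __init__(self, lam: float, K: float):
        self.lam = lam
        self.K = K

    def evalue(self, score: float, m: int, n: int) -> float:
        return self.K * m * n * math.exp(-self.lam * score)

    @classmethod
    def fit(cls, proteins: list[str], config: OrthologyConfig,
            n_decoys: int = 60, seed: int = 0) -> "EvalueModel":
        """Method-of-moments Gumbel fit on scores of shuffled protein pairs."""
        rng = np.random.default_rng(seed)
        aligner = _make_aligner(config)
        pool = [p for p in proteins if len(p) >= 20] or proteins
        scores, mn = [], []
        for _ in range(n_decoys):
            a = list(pool[rng.integers(len(pool))])
            b = list(pool[rng.integers(len(pool))])
            rng.shuffle(a)
            rng.shuffle(b)
            sa, sb = "".join(a), "".join(b)
            scores.append(aligner.score(sa, sb))
            mn.append(len(sa) * len(sb))
        scores = np.asarray(scores, dtype=float)
        var = float(np.var(scores))
        lam = math.pi / math.sqrt(6.0 * max(var, 1e-9))
        euler = 0.5772156649
        mu = float(np.mean(scores)) - euler / lam
        K = math.exp(lam * mu) / float(np.mean(mn))
        return cls(lam, K)


def _kmers(seq: str, k: int) -> set[str]:
    return {seq[i:i + k] for i in range(len(seq) - k + 1)}


def alignment_identity(aln) -> tuple[float, int]:
    """Percent identity over aligned columns including internal gaps."""
    c = aln.counts()
    cols = c.identities + c.mismatches + c.gaps
    if cols == 0:
        return 0.0, 0
    return 100.0 * c.identities / cols, cols


def all_vs_all(
    proteins: list[GeneRecord],
    identity_min: float | None = None,
    evalue_max: float | None = None,
    config: OrthologyConfig | None = None,
    evalue_model: EvalueModel | None = None,
) -> list[Hit]:
    """Local-alignment hits between every cross-genome protein pair.

    A shared-k-mer prefilter keeps the all-vs-all desk-scale; set
    ``config.use_prefilter = False`` to align every pair exhaustively.
    """
    config = config or OrthologyConfig()
    if identity_min is None:
        identity_min = config.identity_min
    if not 0 <= identity_min <= 100:
        raise ValueError("identity_min must lie in [0, 100]")
    if evalue_max is None:
        evalue_max = config.evalue_max

    by_genome: dict[str, list[GeneRecord]] = defaultdict(list)
    for g in proteins:
        by_genome[g.genome_id].append(g)
    if len(by_genome) < 2:
        raise ValueError("all_vs_all needs proteins from at least two genomes")
    for gid, genes in by_genome.items():
        if not any(g.protein for g in genes):
            logger.warning("genome %s has an empty proteome; retained with zero hits", gid)

    aligner = _make_aligner(config)
    model = evalue_model or EvalueModel.fit([g.protein for g in proteins], config)
    kmer_sets = {g.gene_id: _kmers(g.protein, config.kmer_size) for g in proteins}

    hits: list[Hit] = []
    genomes = sorted(by_genome)
    for i, ga in enumerate(genomes):
        for gb in genomes[i + 1:]:
            a_genes, b_genes = by_genome[ga], by_genome[gb]
            if config.use_prefilter:
                inv: dict[str, list[int]] = defaultdict(list)
                for bi, g in enumerate(b_genes):
                    for kmer in kmer_sets[g.gene_id]:
                        inv[kmer].append(bi)
                pairs = []
                for ai, g in enumerate(a_genes):
                    counts = Counter()
                    for kmer in kmer_sets[g.gene_id]:
                        counts.update(inv.get(kmer, ()))
                    pairs.extend((ai, bi) for bi, c in counts.items()
                                 if c >= config.kmer_min_shared)
            else:
                pairs = [(ai, bi) for ai in range(len(a_genes))
                         for bi in range(len(b_genes))]
            for ai, bi in pairs:
                pa, pb = a_genes[ai], b_genes[bi]
                if not pa.protein or not pb.protein:
                    continue
                alns = aligner.align(pa.protein, pb.protein)
                if len(alns) == 0:
                    continue
                aln = alns[0]
                identity, cols = alignment_identity(aln)
                ev = model.evalue(aln.score, len(pa.protein), len(pb.protein))
                if identity >= identity_min and ev <= evalue_max:
                    hits.append(Hit(pa.gene_id, pb.gene_id, ga, gb,
                                    identity, float(aln.score), ev, cols))
                    hits.append(Hit(pb.gene_id, pa.gene_id, gb, ga,
                                    identity, float(aln.score), ev, cols))
    return hits


def reciprocal_best_hits(hits: list[Hit], genome_a: str, genome_b: str) -> list[tuple[str, str]]:
    """Best-reciprocal-hit gene pairs between two genomes.

    Ties on score are broken by higher identity, then lexicographic gene id.
    """
    def _better(h: Hit, cur: Hit) -> bool:
        if h.score != cur.score:
            return h.score > cur.score
        if h.identity != cur.identity:
            return h.identity > cur.identity
        return h.subject_gene < cur.subject_gene

    def best_map(qg: str, sg: str) -> dict[str, str]:
        best: dict[str, Hit] = {}
        for h in hits:
            if h.query_genome != qg or h.subject_genome != sg:
                continue
            cur = best.get(h.query_gene)
            if cur is None or _better(h, cur):
                best[h.query_gene] = h
        return {q: h.subject_gene for q, h in best.items()}

    fwd = best_map(genome_a, genome_b)
    rev = best_map(genome_b, genome_a)
    return sorted((x, y) for x, y in fwd.items() if rev.get(y) == x)


class UnionFind:
    def __init__(self):
        self.parent: dict[str, str] = {}

    def find(self, x: str) -> str:
        self.parent.setdefault(x, x)
        root = x
        while self.parent[root] != root:
            root = self.parent[root]
        while self.parent[x] != root:
            self.parent[x], x = root, self.parent[x]
        return root

    def union(self, a: str, b: str) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[max(ra, rb)] = min(ra, rb)


@dataclass
class OrthologTable:
    """Gene-family membership and the genomes-x-groups phyletic pattern."""

    groups: list[frozenset[str]]
    pattern: pd.DataFrame       # genomes x groups, 0/1
    copy_number: pd.DataFrame   # genomes x groups, gene counts
    identity_min: float
    evalue_max: float

    @property
    def group_ids(self) -> list[str]:
        return list(self.pattern.columns)

    def to_tsv(self, pattern_path, membership_path) -> None:
        self.pattern.to_csv(pattern_path, sep="\t")
        with open(membership_path, "w") as fh:
            fh.write("group_id\tgene_ids\n")
            for gid, members in zip(self.pattern.columns, self.groups):
                fh.write(f"{gid}\t{','.join(sorted(members))}\n")


def build_ortholog_groups(
    rbh_pairs: list[tuple[str, str]],
    proteins: list[GeneRecord],
    config: OrthologyConfig | None = None,
) -> OrthologTable:
    """Ortholog groups as connected components of the RBH graph.

    Every protein appears in exactly one group (unpaired proteins become
    singleton groups).  The phyletic pattern marks group presence per genome.
    """
    config = config or OrthologyConfig()
    genome_of = {g.gene_id: g.genome_id for g in proteins}
    uf = UnionFind()
    for g in proteins:
        uf.find(g.gene_id)
    for x, y in rbh_pairs:
        uf.union(x, y)
    components: dict[str, set[str]] = defaultdict(set)
    for g in proteins:
        components[uf.find(g.gene_id)].add(g.gene_id)
    groups = sorted((frozenset(v) for v in components.values()),
                    key=lambda s: min(s))
    genomes = sorted({g.genome_id for g in proteins})
    group_ids = [f"og{i + 1:05d}" for i in range(len(groups))]
    copy_number = pd.DataFrame(0, index=genomes, columns=group_ids, dtype=int)
    for gid, members in zip(group_ids, groups):
        for gene in members:
            copy_number.loc[genome_of[gene], gid] += 1
    pattern = (copy_number > 0).astype(int)
    return OrthologTable(groups, pattern, copy_number,
                         config.identity_min, config.evalue_max)


def ortholog_table(
    proteins: list[GeneRecord],
    config: OrthologyConfig | None = None,
) -> tuple[OrthologTable, list[Hit]]:
    """Convenience: all-vs-all -> RBH per genome pair -> ortholog groups."""
    config = config or OrthologyConfig()
    hits = all_vs_all(proteins, config=config)
    genomes = sorted({g.genome_id for g in proteins})
    by_pair: dict[tuple[str, str], list[Hit]] = defaultdict(list)
    for h in hits:
        key = tuple(sorted((h.query_genome, h.subject_genome)))
        by_pair[key].append(h)
    pairs: list[tuple[str, str]] = []
    for i, ga in enumerate(genomes):
        for gb in genomes[i + 1:]:
            pairs.extend(reciprocal_best_hits(by_pair.get((ga, gb), []), ga, gb))
    return build_ortholog_groups(pairs, proteins, config), hits


def core_genes(table: OrthologTable) -> list[str]:
    """Groups present in every genome and single-copy in every genome.

    Multi-copy groups are excluded (and logged): unambiguous concatenation
    of one sequence per genome requires single-copy presence.
    """
    if table.pattern.empty:
        raise ValueError("empty ortholog table")
    universal = table.pattern.all(axis=0)
    single = (table.copy_number <= 1).all(axis=0)
    core = [gid for gid in table.pattern.columns if universal[gid] and single[gid]]
    excluded = [gid for gid in table.pattern.columns if universal[gid] and not single[gid]]
    for gid in excluded:
        logger.info("core candidate %s excluded: multi-copy in some genome", gid)
    if not core:
        raise ValueError("empty core gene set; consider lowering the identity threshold")
    return core


def write_hits_tsv(hits: list[Hit], path) -> None:
    """12-column tab-separated hit table (BLAST outfmt-6 compatible layout)."""
    with open(path, "w") as fh:
        for h in hits:
            fh.write("\t".join(map(str, [
                h.query_gene, h.subject_gene, f"{h.identity:.2f}", h.aln_len,
                0, 0, 1, h.aln_len, 1, h.aln_len,
                f"{h.evalue:.3g}", f"{h.score:.1f}"])) + "\n")
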