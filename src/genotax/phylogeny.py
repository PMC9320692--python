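"""Core-genome phylogeny: per-family alignment, concatenation, distance and
tree inference, bootstrap support, and monophyly queries.

The tree's downstream role in the pipeline is (a) the branching order of
candidate species and (b) monophyly tests for the delineation rule, so the
default inference is neighbor joining on Poisson-corrected p-distances of
the concatenated core alignment; a Poisson-model maximum-likelihood search
(exhaustive for small taxon sets, NNI hill-climbing otherwise) is available
for taxon sets up to a configured limit.
"""

from __future__ import annotations

import itertools
import logging
import math
import shutil
import subprocess
import tempfile
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from skbio import DistanceMatrix, TreeNode
from skbio.tree import nj as _skbio_nj

from .config import PhylogenyConfig

logger = logging.getLogger(__name__)

GAP = ord("-")


def read_newick(text: str) -> TreeNode:
    """Parse newick without the underscore-to-space convention (genome ids
    routinely contain underscores)."""
    return TreeNode.read([text], convert_underscores=False)


@dataclass
class CoreAlignment:
    """Concatenated aligned protein blocks, one row per genome."""

    genomes: list[str]
    matrix: np.ndarray                       # uint8 (n_genomes, n_columns)
    partitions: list[tuple[str, int, int]]   # (group id, start, end)

    @property
    def n_columns(self) -> int:
        return self.matrix.shape[1]

    def row(self, genome: str) -> str:
        return self.matrix[self.genomes.index(genome)].tobytes().decode()

    def to_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for name in self.genomes:
                fh.write(f">{name}\n{self.row(name)}\n")

    def to_phylip(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"{len(self.genomes)} {self.n_columns}\n")
            for name in self.genomes:
                fh.write(f"{name}  {self.row(name)}\n")


def align_family(seqs: dict[str, str]) -> dict[str, str]:
    """Multiple alignment of one protein family (MAFFT; deterministic).

    A single sequence is returned unchanged.  Sequences of identical length
    that are already column-comparable are common for conserved families and
    come back gap-free.
    """
    if len(seqs) == 1:
        return dict(seqs)
    if shutil.which("mafft") is None:
        raise RuntimeError("mafft is required for multiple alignment")
    order = list(seqs)
    with tempfile.TemporaryDirectory() as tmp:
        infile = Path(tmp) / "in.fasta"
        with open(infile, "w") as fh:
            for i, name in enumerate(order):
                fh.write(f">s{i}\n{seqs[name]}\n")
        out = subprocess.run(["mafft", "--quiet", "--auto", str(infile)],
                             check=True, capture_output=True, text=True).stdout
    aligned: dict[str, str] = {}
    current = None
    chunks: list[str] = []
    for line in out.splitlines():
        if line.startswith(">"):
            if current is not None:
                aligned[current] = "".join(chunks)
            current = line[1:].strip()
            chunks = []
        else:
            chunks.append(line.strip())
    if current is not None:
        aligned[current] = "".join(chunks)
    return {name: aligned[f"s{i}"].upper() for i, name in enumerate(order)}


def concatenate(blocks: dict[str, dict[str, str]],
                genomes: list[str] | None = None) -> CoreAlignment:
    """Join aligned family blocks in sorted group-id order.

    Every block must cover every genome exactly once; the partition spans of
    the concatenation are recorded.
    """
    if not blocks:
        raise ValueError("no aligned blocks to concatenate")
    if genomes is None:
        genomes = sorted(next(iter(blocks.values())))
    parts: list[tuple[str, int, int]] = []
    rows = {g: [] for g in genomes}
    pos = 0
    for gid in sorted(blocks):
        block = blocks[gid]
        missing = set(genomes) - set(block)
        if missing:
            raise ValueError(f"block {gid} missing genomes: {sorted(missing)}")
        width = len(next(iter(block.values())))
        if any(len(block[g]) != width for g in genomes):
            raise ValueError(f"block {gid} rows differ in length")
        for g in genomes:
            rows[g].append(block[g])
        parts.append((gid, pos, pos + width))
        pos += width
    matrix = np.array([np.frombuffer("".join(rows[g]).encode(), dtype=np.uint8)
                       for g in genomes])
    return CoreAlignment(list(genomes), matrix, parts)


def distance_matrix(aln: CoreAlignment) -> DistanceMatrix:
    """Poisson-corrected pairwise distances, pairwise gap deletion.

    p is the mismatch fraction over columns where neither row has a gap;
    d = -ln(1 - p).  p >= 1 (or numerically so) is capped with a warning.
    """
    n = len(aln.genomes)
    if n < 2:
        raise ValueError("need at least two rows")
    M = aln.matrix
    dist = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        valid = (M[i] != GAP) & (M[j] != GAP)
        nv = int(valid.sum())
        if nv == 0:
            raise ValueError(
                f"no comparable columns between {aln.genomes[i]} and {aln.genomes[j]}")
        p = float(np.mean(M[i][valid] != M[j][valid]))
        if p >= 1.0 - 1e-12:
            logger.warning("p-distance saturated for %s vs %s; capped",
                           aln.genomes[i], aln.genomes[j])
            p = 1.0 - 1e-12
        dist[i, j] = dist[j, i] = -math.log1p(-p)
    return DistanceMatrix(dist, ids=aln.genomes)


@dataclass
class PhyloTree:
    """Leaf-labeled tree with branch lengths and optional bootstrap support."""

    tree: TreeNode

    @property
    def leaf_names(self) -> list[str]:
        return sorted(n.name for n in self.tree.tips())

    def newick(self) -> str:
        return str(self.tree).strip()

    def write(self, path) -> None:
        self.tree.write(str(path))

    def bipartitions(self) -> set[frozenset[str]]:
        """Non-trivial bipartitions, each as the frozenset of the smaller side
        (ties broken by lexicographic minimum) over the full leaf set."""
        leaves = frozenset(self.leaf_names)
        out = set()
        for node in self.tree.non_tips(include_self=False):
            side = frozenset(t.name for t in node.tips())
            if 1 < len(side) < len(leaves) - 1:
                out.add(_canonical(side, leaves))
        return out

    def is_monophyletic(self, leafset) -> bool:
        """True iff one edge of the unrooted tree separates exactly ``leafset``.

        Singletons and the full leaf set are trivially monophyletic.
        """
        leaves = frozenset(self.leaf_names)
        query = frozenset(leafset)
        unknown = query - leaves
        if unknown:
            raise ValueError(f"unknown leaves: {sorted(unknown)}")
        if len(query) <= 1 or query == leaves:
            return True
        if len(query) == len(leaves) - 1:
            return True      # complement of a single leaf's pendant edge
        return _canonical(query, leaves) in self.bipartitions()

    def clades(self) -> list[frozenset[str]]:
        """Every leaf subset cut off by a single edge (both sides of each
        bipartition, plus singletons and the full set)."""
        leaves = frozenset(self.leaf_names)
        out = {leaves} | {frozenset([x]) for x in leaves}
        for side in self.bipartitions():
            out.add(side)
            out.add(leaves - side)
        return sorted(out, key=lambda s: (-len(s), sorted(s)))

    def rf_distance(self, other: "PhyloTree") -> int:
        return len(self.bipartitions() ^ other.bipartitions())

    def is_refinement_of(self, other: "PhyloTree") -> bool:
        """True iff every bipartition of ``other`` is present here.

        A fully resolved estimate of a tree with multifurcations (e.g. a
        star of equidistant strains, where no resolution is wrong) refines
        the true tree without matching it edge-for-edge.
        """
        return other.bipartitions() <= self.bipartitions()

    def root_with_outgroup(self, outgroup: list[str]) -> "PhyloTree":
        tips = [self.tree.find(name) for name in outgroup]
        node = self.tree.lowest_common_ancestor(tips) if len(tips) > 1 else tips[0]
        return PhyloTree(self.tree.root_at(node.parent))


def _canonical(side: frozenset[str], leaves: frozenset[str]) -> frozenset[str]:
    comp = leaves - side
    if len(side) < len(comp):
        return side
    if len(comp) < len(side):
        return comp
    return side if min(side) < min(comp) else comp


def nj_tree(dm: DistanceMatrix) -> PhyloTree:
    """Neighbor joining; negative branch lengths are clamped to zero."""
    tree = _skbio_nj(dm, neg_as_zero=True)
    return PhyloTree(tree)


def infer_tree(aln: CoreAlignment, method: str = "nj",
               config: PhylogenyConfig | None = None) -> PhyloTree:
    """Infer the core-genome tree.

    ``nj``: neighbor joining on the Poisson-corrected distance matrix.
    ``ml_poisson``: topology search maximizing the likelihood under a
    Poisson amino-acid model — exhaustive for <= 6 taxa, NNI hill-climbing
    from the NJ tree otherwise; refused above ``config.ml_max_taxa``.
    """
    config = config or PhylogenyConfig()
    if len(aln.genomes) < 3:
        raise ValueError("tree inference needs at least three genomes")
    if method == "nj":
        return nj_tree(distance_matrix(aln))
    if method == "ml_poisson":
        if len(aln.genomes) > config.ml_max_taxa:
            raise ValueError(
                f"ml_poisson limited to {config.ml_max_taxa} taxa; use method='nj'")
        return _ml_poisson(aln)
    raise ValueError(f"unknown method {method!r}")


# ---------------------------------------------------------------------------
# Poisson-model maximum likelihood (desk scale)

_AA = "ACDEFGHIKLMNPQRSTVWY"
_AA_IDX = {ord(a): i for i, a in enumerate(_AA)}
N_STATES = 20


def _compress(aln: CoreAlignment) -> tuple[np.ndarray, np.ndarray]:
    """Site-pattern compression; unknown characters become state -1 (ignored)."""
    cols = aln.matrix.T
    states = np.full(cols.shape, -1, dtype=np.int8)
    for byte, idx in _AA_IDX.items():
        states[cols == byte] = idx
    patterns, counts = np.unique(states, axis=0, return_counts=True)
    return patterns, counts.astype(float)


def _pmatrix(t: float) -> np.ndarray:
    """Poisson (equal-rates, equal-frequencies) transition matrix."""
    e = math.exp(-N_STATES * t / (N_STATES - 1))
    off = (1.0 - e) / N_STATES
    P = np.full((N_STATES, N_STATES), off)
    np.fill_diagonal(P, off + e)
    return P


class _MLTree:
    """Unrooted topology over leaf names, likelihood via Felsenstein pruning."""

    def __init__(self, topology: tuple, patterns: np.ndarray, counts: np.ndarray,
                 leaf_order: list[str]):
        self.topology = topology
        self.patterns = patterns
        self.counts = counts
        self.leaf_idx = {name: i for i, name in enumerate(leaf_order)}
        self.edges = _edges_of(topology)

    def loglik(self, lengths: np.ndarray) -> float:
        blen = dict(zip(self.edges, np.maximum(lengths, 1e-8)))
        n_pat = self.patterns.shape[0]

        def partial(node, parent) -> np.ndarray:
            if isinstance(node, str):
                states = self.patterns[:, self.leaf_idx[node]]
                L = np.ones((n_pat, N_STATES))
                known = states >= 0
                L[known] = 0.0
                L[known, states[known]] = 1.0
            else:
                L = np.ones((n_pat, N_STATES))
                for child in node:
                    if child is parent:
                        continue
                    Lc = partial(child, node)
                    P = _pmatrix(blen[_edge_key(node, child)])
                    L = L * (Lc @ P.T)
            return L

        root = self.topology
        L = np.ones((n_pat, N_STATES))
        for child in root:
            Lc = partial(child, root)
            P = _pmatrix(blen[_edge_key(root, child)])
            L = L * (Lc @ P.T)
        site = (L.sum(axis=1) / N_STATES)
        return float(np.sum(self.counts * np.log(np.maximum(site, 1e-300))))

    def optimize(self) -> tuple[float, np.ndarray]:
        from scipy.optimize import minimize
        x0 = np.full(len(self.edges), 0.1)
        res = minimize(lambda x: -self.loglik(x), x0, method="L-BFGS-B",
                       bounds=[(1e-8, 10.0)] * len(self.edges),
                       options={"maxiter": 200})
        return -res.fun, res.x


def _edge_key(a, b):
    return (id(a), id(b)) if id(a) < id(b) else (id(b), id(a))


def _edges_of(topology) -> list:
    edges = []

    def walk(node, parent):
        if parent is not None:
            edges.append(_edge_key(parent, node))
        if not isinstance(node, str):
            for child in node:
                walk(child, node)

    walk(topology, None)
    return edges


def _all_topologies(names: list[str]):
    """All unrooted binary topologies by stepwise addition (nested tuples)."""
    if len(names) == 3:
        yield (names[0], names[1], names[2])
        return

    def insert_all(node, leaf):
        # returns list of topologies with `leaf` inserted on every edge below node
        results = []
        if isinstance(node, tuple):
            for i, child in enumerate(node):
                for sub in insert_all(child, leaf):
                    results.append(tuple(sub if j == i else c
                                         for j, c in enumerate(node)))
        results.append((node, leaf))
        return results

    base = (names[0], names[1], names[2])
    tops = [base]
    for leaf in names[3:]:
        new = []
        for top in tops:
            for i, child in enumerate(top):
                for sub in insert_all(child, leaf):
                    new.append(tuple(sub if j == i else c for j, c in enumerate(top)))
        tops = new
    yield from tops


def _topology_to_newick(node) -> str:
    if isinstance(node, str):
        return node
    return "(" + ",".join(_topology_to_newick(c) for c in node) + ")"


def _ml_poisson(aln: CoreAlignment) -> PhyloTree:
    patterns, counts = _compress(aln)
    names = list(aln.genomes)
    best = (-math.inf, None, None)
    if len(names) <= 6:
        candidates = list(_all_topologies(names))
    else:
        start = nj_tree(distance_matrix(aln))
        candidates = [_newick_to_topology(start.tree)]
    improved = True
    while improved:
        improved = False
        for top in candidates:
            mlt = _MLTree(top, patterns, counts, names)
            ll, lengths = mlt.optimize()
            if ll > best[0]:
                best = (ll, top, (mlt, lengths))
                improved = len(names) > 6   # keep NNI-ing around a new optimum
        if improved:
            candidates = _nni_neighbors(best[1])
    ll, top, (mlt, lengths) = best
    blen = dict(zip(mlt.edges, lengths))
    nwk = _topology_newick_with_lengths(top, None, blen) + ";"
    return PhyloTree(read_newick(nwk))


def _topology_newick_with_lengths(node, parent, blen) -> str:
    if isinstance(node, str):
        label = node
    else:
        label = "(" + ",".join(_topology_newick_with_lengths(c, node, blen)
                               for c in node) + ")"
    if parent is None:
        return label
    return f"{label}:{blen[_edge_key(parent, node)]:.6g}"


def _newick_to_topology(tree: TreeNode):
    def conv(node):
        if node.is_tip():
            return node.name
        return tuple(conv(c) for c in node.children)
    top = conv(tree)
    if len(top) == 2:       # rooted binary -> unrooted trifurcation
        a, b = top
        if isinstance(a, tuple):
            top = a + (b,)
        else:
            top = (a,) + b
    return top


def _topology_to_adjacency(topology):
    """Nested-tuple topology -> (adjacency dict over int nodes, leaf labels)."""
    adj: dict[int, list[int]] = {}
    labels: dict[int, str] = {}
    counter = itertools.count()

    def walk(node) -> int:
        nid = next(counter)
        adj[nid] = []
        if isinstance(node, str):
            labels[nid] = node
        else:
            for child in node:
                cid = walk(child)
                adj[nid].append(cid)
                adj[cid].append(nid)
        return nid

    walk(topology)
    return adj, labels


def _adjacency_to_topology(adj, labels, root=0):
    def walk(node, parent):
        if node in labels:
            return labels[node]
        return tuple(walk(c, node) for c in adj[node] if c != parent)

    return walk(root, None)


def _nni_neighbors(topology):
    """All topologies one nearest-neighbor interchange away (unrooted)."""
    adj, labels = _topology_to_adjacency(topology)
    out = []
    internal = [n for n in adj if n not in labels]
    for u in internal:
        for v in adj[u]:
            if v in labels or v < u:
                continue
            u_subs = [x for x in adj[u] if x != v]
            v_subs = [x for x in adj[v] if x != u]
            # swapping one subtree from each side; two distinct exchanges
            for a in u_subs[:1]:
                for b in v_subs:
                    adj2 = {k: list(vv) for k, vv in adj.items()}
                    adj2[u].remove(a); adj2[v].remove(b)
                    adj2[u].append(b); adj2[v].append(a)
                    adj2[a].remove(u); adj2[a].append(v)
                    adj2[b].remove(v); adj2[b].append(u)
                    out.append(_adjacency_to_topology(adj2, labels, root=internal[0]))
    return out


# ---------------------------------------------------------------------------
# Bootstrap

def bootstrap_support(aln: CoreAlignment, method: str = "nj",
                      replicates: int = 100, seed: int = 0,
                      config: PhylogenyConfig | None = None) -> tuple[PhyloTree, dict[frozenset[str], float]]:
    """Bootstrap support for the point-estimate tree.

    Columns of the concatenated alignment are resampled with replacement
    (ignoring partition boundaries) per replicate; the support of each
    bipartition of the point tree is the percentage of replicate trees
    containing it.  Support values are written to the internal nodes of the
    returned tree.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    point = infer_tree(aln, method=method, config=config)
    target = point.bipartitions()
    rng = np.random.default_rng(seed)
    n = len(aln.genomes)
    L = aln.n_columns
    M = aln.matrix
    pairs = list(itertools.combinations(range(n), 2))
    mis = np.array([(M[i] != M[j]) & (M[i] != GAP) & (M[j] != GAP) for i, j in pairs],
                   dtype=float)
    val = np.array([(M[i] != GAP) & (M[j] != GAP) for i, j in pairs], dtype=float)
    counts_hit = {bp: 0 for bp in target}
    for _ in range(replicates):
        w = np.bincount(rng.integers(0, L, size=L), minlength=L).astype(float)
        p = (mis @ w) / np.maximum(val @ w, 1.0)
        p = np.minimum(p, 1.0 - 1e-12)
        d = -np.log1p(-p)
        dist = np.zeros((n, n))
        for (i, j), dij in zip(pairs, d):
            dist[i, j] = dist[j, i] = dij
        rep = nj_tree(DistanceMatrix(dist, ids=aln.genomes))
        for bp in rep.bipartitions() & target:
            counts_hit[bp] += 1
    support = {bp: 100.0 * c / replicates for bp, c in counts_hit.items()}
    _annotate_support(point, support)
    return point, support


def _annotate_support(tree: PhyloTree, support: dict[frozenset[str], float]) -> None:
    leaves = frozenset(tree.leaf_names)
    for node in tree.tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if 1 < len(side) < len(leaves) - 1:
            node.name = f"{support.get(_canonical(side, leaves), 0.0):g}"
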