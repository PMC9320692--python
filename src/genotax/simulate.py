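"""Synthetic bacterial genome sets with known evolutionary truth.

The generator evolves a clade of genomes along a known ultrametric tree so
that every downstream stage of the pipeline can be checked against ground
truth: the true tree, the true species partition, the realized per-pair
substitution fraction (hence the true ANI regime), and the true gene-family
presence/absence table.

Model in brief
--------------
* An ancestor genome of ``n_genes`` protein-coding genes (ATG + random sense
  codons + TAA) separated by intergenic spacers, with a configurable GC bias.
* A pure-birth species topology; strain subtrees attach at height t_w/2 and
  species splits at heights from t_b/2 upward, where t = -(3/4)ln(1 - 4p/3)
  converts a target observed divergence p into Jukes-Cantor path time.  The
  shallowest between-species pair therefore shows exactly
  ``between_divergence`` expected substitutions per site; deeper pairs more.
* Substitutions are i.i.d. Jukes-Cantor events per branch.  Codon positions
  1/2/3 carry rate weights 0.6/0.6/1.8 (mean 1), so proteins diverge more
  slowly than nucleotides; substitutions that would create an in-frame stop
  codon are redrawn among non-stop bases, keeping every gene a clean ORF.
* Gene loss removes a gene's DNA; gene gain inserts a novel random gene with
  no homology to anything else, so orthology cannot cross-link gains.  An
  optional HGT mode copies an evolved gene between lineages instead.
* Each genome is finally split into ``n_contigs`` contigs at intergenic
  points.

All randomness flows from the single ``seed`` in :class:`SimConfig`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import SimConfig
from .genome_io import GeneRecord, GenomeRecord, translate_cds

BASES = "ACGT"
STOPS = {"TAA", "TAG", "TGA"}
_STOP_CODES = {tuple(BASES.index(c) for c in s) for s in STOPS}

POS_WEIGHTS = (0.6, 0.6, 1.8)  # codon positions 1, 2, 3
INTERGENIC_WEIGHT = 1.0


def jc_time(p: float) -> float:
    """Jukes-Cantor path time giving expected observed divergence ``p``."""
    if not 0 <= p < 0.75:
        raise ValueError("observed divergence must lie in [0, 0.75)")
    return -0.75 * math.log1p(-4.0 * p / 3.0)


def jc_expected_p(t: float) -> float:
    """Expected observed divergence after Jukes-Cantor path time ``t``."""
    return 0.75 * (1.0 - math.exp(-4.0 * t / 3.0))


@dataclass
class SimNode:
    name: str
    height: float                      # distance to the leaf level
    children: list["SimNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["SimNode"]:
        if self.is_leaf:
            return [self]
        out = []
        for c in self.children:
            out.extend(c.leaves())
        return out

    def newick(self) -> str:
        return self._nwk(self.height) + ";"

    def _nwk(self, parent_height: float) -> str:
        bl = parent_height - self.height
        if self.is_leaf:
            return f"{self.name}:{bl:.10g}"
        inner = ",".join(c._nwk(self.height) for c in self.children)
        return f"({inner}):{bl:.10g}"


@dataclass
class SimTree:
    root: SimNode
    partition: dict[str, str]          # strain -> species label

    @property
    def newick(self) -> str:
        return self.root.newick()

    def leaf_names(self) -> list[str]:
        return [n.name for n in self.root.leaves()]

    def path_time(self, a: str, b: str) -> float:
        """Total Jukes-Cantor time on the path between two leaves."""
        if a == b:
            return 0.0
        anc = self._mrca(self.root, {a, b})
        return 2.0 * anc.height - self._leaf_height(anc, a) - self._leaf_height(anc, b)

    def _mrca(self, node: SimNode, targets: set[str]) -> SimNode:
        for child in node.children:
            names = {leaf.name for leaf in child.leaves()}
            if targets <= names:
                return self._mrca(child, targets)
        return node

    @staticmethod
    def _leaf_height(node: SimNode, name: str) -> float:
        for leaf in node.leaves():
            if leaf.name == name:
                return leaf.height
        raise KeyError(name)

    def expected_divergence(self, a: str, b: str) -> float:
        """Expected observed substitution fraction for an unweighted site."""
        return jc_expected_p(self.path_time(a, b))


def simulate_tree(config: SimConfig) -> SimTree:
    """Species tree with strain subtrees, calibrated to the target divergences.

    Within-species strain pairs have Jukes-Cantor path time t(within) exactly;
    the shallowest between-species pair has t(between); deeper species splits
    are spaced up to 1.3x that height, so all between-species divergences are
    at least ``between_divergence``.
    """
    rng = np.random.default_rng(config.seed)
    t_w = jc_time(config.within_divergence)
    t_b = jc_time(config.between_divergence)
    if config.n_species > 1 and t_b < t_w:
        raise ValueError("between_divergence must be >= within_divergence")

    partition: dict[str, str] = {}
    roots: list[SimNode] = []
    for si in range(config.n_species):
        strains = []
        for sj in range(config.strains_per_species):
            name = f"sp{si + 1}_st{sj + 1}"
            partition[name] = f"sp{si + 1}"
            strains.append(SimNode(name, 0.0))
        if len(strains) == 1:
            node = strains[0]
        else:
            node = SimNode(f"sp{si + 1}", t_w / 2.0, strains)
        roots.append(node)

    n_joins = config.n_species - 1
    for k in range(n_joins):
        if n_joins > 1:
            h = (t_b / 2.0) * (1.0 + 0.3 * k / (n_joins - 1))
        else:
            h = t_b / 2.0
        i, j = sorted(rng.choice(len(roots), size=2, replace=False))
        merged = SimNode(f"anc{k + 1}", h, [roots[i], roots[j]])
        roots = [r for idx, r in enumerate(roots) if idx not in (i, j)]
        roots.append(merged)
    return SimTree(roots[0], partition)


@dataclass
class SimTruth:
    """Everything the simulator knows that the pipeline must rediscover."""

    tree_newick: str
    partition: dict[str, str]
    pair_substitution: dict[tuple[str, str], float]
    pair_expected: dict[tuple[str, str], float]
    presence: pd.DataFrame             # genomes x families, 0/1
    proteins: dict[str, dict[str, str]]  # family -> genome -> protein
    path_times: dict[tuple[str, str], float]
    ancestral_families: list[str]
    families_untouched_by_loss: list[str]
    hgt_events: list[tuple[str, str, str]] = None   # (donor, recipient, family)

    def true_ani(self, a: str, b: str) -> float:
        """100*(1 - realized substitution fraction on shared homologous sites)."""
        if a == b:
            return 100.0
        return 100.0 * (1.0 - self.pair_substitution[_key(a, b)])


def _key(a: str, b: str) -> tuple[str, str]:
    return (a, b) if a <= b else (b, a)


def _random_gene(rng: np.random.Generator, gene_len: int, probs: np.ndarray) -> np.ndarray:
    """ATG + random non-stop codons + TAA, encoded as uint8 over ACGT."""
    n_codons = gene_len // 3
    seq = np.empty(gene_len, dtype=np.uint8)
    seq[:3] = [0, 3, 2]                # ATG
    for ci in range(1, n_codons - 1):
        while True:
            codon = rng.choice(4, size=3, p=probs)
            if tuple(codon) not in _STOP_CODES:
                break
        seq[3 * ci:3 * ci + 3] = codon
    seq[-3:] = [3, 0, 0]               # TAA
    return seq


class _GenomeState:
    """Mutable per-lineage state carried down the tree."""

    def __init__(self, seq: np.ndarray, deleted: np.ndarray,
                 present: set[str], gained: list[tuple[str, np.ndarray]]):
        self.seq = seq
        self.deleted = deleted
        self.present = present
        self.gained = gained

    def copy(self) -> "_GenomeState":
        return _GenomeState(self.seq.copy(), self.deleted.copy(),
                            set(self.present), [(g, s.copy()) for g, s in self.gained])


class _Ancestor:
    def __init__(self, config: SimConfig, rng: np.random.Generator):
        gc = config.gc
        self.probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
        L = config.n_genes * (config.gene_len + config.intergenic_len) + config.intergenic_len
        self.length = L
        self.weights = np.full(L, INTERGENIC_WEIGHT)
        self.seq = np.empty(L, dtype=np.uint8)
        # codon bookkeeping for stop avoidance: -1 outside protected codons
        self.codon_start = np.full(L, -1, dtype=np.int64)
        self.gene_spans: list[tuple[str, int, int]] = []
        pos = 0

        def spacer(n: int) -> np.ndarray:
            return rng.choice(4, size=n, p=self.probs).astype(np.uint8)

        self.seq[pos:pos + config.intergenic_len] = spacer(config.intergenic_len)
        pos += config.intergenic_len
        for gi in range(config.n_genes):
            fam = f"fam{gi + 1:04d}"
            gene = _random_gene(rng, config.gene_len, self.probs)
            self.seq[pos:pos + config.gene_len] = gene
            self.gene_spans.append((fam, pos, pos + config.gene_len))
            body = np.arange(pos, pos + config.gene_len)
            self.weights[body] = np.tile(POS_WEIGHTS, config.gene_len // 3)
            # every codon except the terminal stop is protected from becoming a stop
            interior = body[: config.gene_len - 3]
            self.codon_start[interior] = pos + 3 * ((interior - pos) // 3)
            pos += config.gene_len
            self.seq[pos:pos + config.intergenic_len] = spacer(config.intergenic_len)
            pos += config.intergenic_len
        assert pos == L
        self.intergenic_mask = np.ones(L, dtype=bool)
        for _, s, e in self.gene_spans:
            self.intergenic_mask[s:e] = False
        # first-order correction for stop avoidance: at a protected site with
        # a allowed bases, P(change | event) is (a-1)/a instead of 3/4
        self.change_factor = np.ones(L)
        prot = np.flatnonzero(self.codon_start >= 0)
        for site in prot:
            cs = self.codon_start[site]
            codon = [int(self.seq[cs]), int(self.seq[cs + 1]), int(self.seq[cs + 2])]
            off = site - cs
            a = sum(1 for b in range(4)
                    if tuple(codon[:off] + [b] + codon[off + 1:]) not in _STOP_CODES)
            self.change_factor[site] = ((a - 1) / a) / 0.75


def _mutate(state: _GenomeState, anc: _Ancestor, t: float,
            rng: np.random.Generator) -> None:
    q = 1.0 - np.exp(-(4.0 / 3.0) * anc.weights * t)
    events = np.flatnonzero(rng.random(anc.length) < q)
    protected = events[anc.codon_start[events] >= 0]
    free = events[anc.codon_start[events] < 0]
    state.seq[free] = rng.choice(4, size=free.size).astype(np.uint8)
    for site in protected:
        cs = anc.codon_start[site]
        codon = [int(state.seq[cs]), int(state.seq[cs + 1]), int(state.seq[cs + 2])]
        off = site - cs
        allowed = []
        for b in range(4):
            cand = codon.copy()
            cand[off] = b
            if tuple(cand) not in _STOP_CODES:
                allowed.append(b)
        state.seq[site] = allowed[rng.integers(len(allowed))]
    # gained genes carry the same codon weighting and stop avoidance
    gene_len = None
    for _, gseq in state.gained:
        gene_len = gseq.size
        w = np.tile(POS_WEIGHTS, gene_len // 3)
        qg = 1.0 - np.exp(-(4.0 / 3.0) * w * t)
        for site in np.flatnonzero(rng.random(gene_len) < qg):
            if site >= gene_len - 3:
                gseq[site] = rng.integers(4)
                continue
            cs = 3 * (site // 3)
            codon = [int(gseq[cs]), int(gseq[cs + 1]), int(gseq[cs + 2])]
            off = site - cs
            allowed = [b for b in range(4)
                       if tuple(codon[:off] + [b] + codon[off + 1:]) not in _STOP_CODES]
            gseq[site] = allowed[rng.integers(len(allowed))]


def _decode(arr: np.ndarray) -> str:
    return "".join(BASES[b] for b in arr)


def evolve_genomes(
    tree: SimTree, config: SimConfig
) -> tuple[list[GenomeRecord], dict[str, list[GeneRecord]], SimTruth]:
    """Evolve genomes along ``tree`` and emit assemblies, annotations, truth.

    Returns genome records (multi-contig), per-genome CDS annotation tables,
    and a :class:`SimTruth` with the realized per-pair substitution fractions
    (computed over ancestral positions retained in both genomes), the gene
    presence/absence table, and per-family protein sets.
    """
    rng = np.random.default_rng(config.seed + 1)
    anc = _Ancestor(config, rng)
    root_state = _GenomeState(anc.seq.copy(), np.zeros(anc.length, dtype=bool),
                              {fam for fam, _, _ in anc.gene_spans}, [])
    leaf_states: dict[str, _GenomeState] = {}
    gain_counter = [0]
    span_of = {fam: (s, e) for fam, s, e in anc.gene_spans}

    def descend(node: SimNode, state: _GenomeState, parent_height: float) -> None:
        t = parent_height - node.height
        if t > 0:
            _mutate(state, anc, t, rng)
            n_loss = rng.poisson(config.gene_loss_rate)
            losable = sorted(state.present)
            for fam in rng.choice(losable, size=min(n_loss, len(losable)), replace=False):
                s, e = span_of[fam]
                state.deleted[s:e] = True
                state.present.discard(fam)
            for _ in range(rng.poisson(config.gene_gain_rate)):
                gain_counter[0] += 1
                gid = f"gain{gain_counter[0]:04d}"
                state.gained.append((gid, _random_gene(rng, config.gene_len, anc.probs)))
        if node.is_leaf:
            if not state.present and not state.gained:
                raise ValueError(f"genome {node.name} lost every gene; lower gene_loss_rate")
            leaf_states[node.name] = state
        else:
            for child in node.children:
                descend(child, state.copy() if len(node.children) > 1 else state,
                        node.height)

    # root branch has length 0 (root height to itself)
    descend(tree.root, root_state, tree.root.height)

    hgt_events: list[tuple[str, str, str]] = []
    if config.hgt_rate > 0:
        hgt_events = _apply_hgt(tree, leaf_states, span_of, config, rng)

    leaf_names = tree.leaf_names()
    genomes: list[GenomeRecord] = []
    annotations: dict[str, list[GeneRecord]] = {}
    presence_rows = {}
    proteins: dict[str, dict[str, str]] = {}

    for name in leaf_names:
        st = leaf_states[name]
        genome, genes = _emit(name, st, anc, config, rng)
        genomes.append(genome)
        annotations[name] = genes
        row = {}
        for fam in st.present:
            row[fam] = 1
        for gid, _ in st.gained:
            row[gid] = 1
        presence_rows[name] = row
        for g in genes:
            proteins.setdefault(g.gene_id.rsplit("|", 1)[0], {})[name] = g.protein

    all_fams = sorted({f for row in presence_rows.values() for f in row})
    presence = pd.DataFrame(0, index=leaf_names, columns=all_fams, dtype=int)
    for name, row in presence_rows.items():
        for fam in row:
            presence.loc[name, fam] = 1

    pair_sub: dict[tuple[str, str], float] = {}
    pair_exp: dict[tuple[str, str], float] = {}
    path_times: dict[tuple[str, str], float] = {}
    for i, a in enumerate(leaf_names):
        for b in leaf_names[i + 1:]:
            sa, sb = leaf_states[a], leaf_states[b]
            mask = ~sa.deleted & ~sb.deleted
            pair_sub[_key(a, b)] = float(np.mean(sa.seq[mask] != sb.seq[mask]))
            T = tree.path_time(a, b)
            path_times[_key(a, b)] = T
            # site-weight-aware closed form, averaged over the shared sites
            pair_exp[_key(a, b)] = float(np.mean(
                anc.change_factor[mask] * 0.75
                * (1.0 - np.exp(-(4.0 / 3.0) * anc.weights[mask] * T))))

    ancestral = [fam for fam, _, _ in anc.gene_spans]
    untouched = [fam for fam in ancestral
                 if all(fam in leaf_states[n].present for n in leaf_names)]
    truth = SimTruth(
        tree_newick=tree.newick,
        partition=dict(tree.partition),
        pair_substitution=pair_sub,
        pair_expected=pair_exp,
        presence=presence,
        proteins=proteins,
        path_times=path_times,
        ancestral_families=ancestral,
        families_untouched_by_loss=untouched,
        hgt_events=hgt_events,
    )
    return genomes, annotations, truth


def _apply_hgt(tree: SimTree, leaf_states: dict[str, _GenomeState],
               span_of: dict[str, tuple[int, int]], config: SimConfig,
               rng: np.random.Generator) -> list[tuple[str, str, str]]:
    """Copy evolved genes between lineages, creating phyletic discordance."""
    names = tree.leaf_names()
    n_events = rng.poisson(config.hgt_rate * len(names))
    events = []
    for _ in range(n_events):
        donor, recipient = rng.choice(names, size=2, replace=False)
        donor_st, recip_st = leaf_states[donor], leaf_states[recipient]
        candidates = sorted(donor_st.present - recip_st.present)
        if not candidates:
            continue
        fam = candidates[rng.integers(len(candidates))]
        s, e = span_of[fam]
        recip_st.gained.append((fam, donor_st.seq[s:e].copy()))
        recip_st.present.add(fam)
        events.append((str(donor), str(recipient), fam))
    return events


def _emit(name: str, st: _GenomeState, anc: _Ancestor, config: SimConfig,
          rng: np.random.Generator) -> tuple[GenomeRecord, list[GeneRecord]]:
    keep = ~st.deleted
    kept_idx = np.flatnonzero(keep)
    new_pos = np.cumsum(keep) - 1       # ancestral -> current coordinate
    core_seq = st.seq[keep]

    # append gained genes after the last ancestral position, spacer-separated
    tail_parts = []
    gained_coords = []
    tail_pos = core_seq.size
    for gid, gseq in st.gained:
        spacer = rng.choice(4, size=config.intergenic_len, p=anc.probs).astype(np.uint8)
        tail_parts.extend([spacer, gseq])
        start = tail_pos + config.intergenic_len
        gained_coords.append((gid, start, start + gseq.size))
        tail_pos = start + gseq.size
    full = np.concatenate([core_seq] + tail_parts) if tail_parts else core_seq

    # contig boundaries at intergenic, non-deleted, current positions
    eligible = kept_idx[anc.intergenic_mask[kept_idx]]
    eligible_current = new_pos[eligible]
    n_cuts = max(0, config.n_contigs - 1)
    cuts = sorted(rng.choice(eligible_current, size=n_cuts, replace=False)) if n_cuts else []
    bounds = [0] + [int(c) for c in cuts] + [full.size]
    contigs = []
    for k in range(len(bounds) - 1):
        s, e = bounds[k], bounds[k + 1]
        if e > s:
            contigs.append((f"{name}_c{k + 1}", _decode(full[s:e])))
    genome = GenomeRecord(genome_id=name, contigs=contigs, source="simulated")

    def locate(start: int, end: int) -> tuple[str, int, int]:
        for k in range(len(bounds) - 1):
            if bounds[k] <= start and end <= bounds[k + 1]:
                return contigs[k][0], start - bounds[k], end - bounds[k]
        raise AssertionError("gene straddles a contig boundary")

    genes: list[GeneRecord] = []
    for fam, s, e in anc.gene_spans:
        # a family can be "present" through a transferred copy while its
        # ancestral span is deleted; only intact spans are emitted here
        if fam not in st.present or st.deleted[s]:
            continue
        cur_s, cur_e = int(new_pos[s]), int(new_pos[e - 1]) + 1
        cid, gs, ge = locate(cur_s, cur_e)
        nt = _decode(full[cur_s:cur_e])
        genes.append(GeneRecord(f"{fam}|{name}", name, cid, gs, ge, "+",
                                translate_cds(nt)))
    for gid, gstart, gend in gained_coords:
        cid, gs, ge = locate(gstart, gend)
        nt = _decode(full[gstart:gend])
        genes.append(GeneRecord(f"{gid}|{name}", name, cid, gs, ge, "+",
                                translate_cds(nt)))
    return genome, genes


def simulate(config: SimConfig):
    """Convenience wrapper: tree + genomes + annotations + truth."""
    tree = simulate_tree(config)
    genomes, annotations, truth = evolve_genomes(tree, config)
    return tree, genomes, annotations, truth
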