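"""Fragment-based average nucleotide identity (ANIb) and dDDH estimates.

ANIb follows the JSpecies/Goris convention: the query genome is cut into
consecutive 1020-nt fragments, each fragment is aligned to the subject
genome, and fragments are retained only if they align at >= 30% identity
over >= 70% of their length; the ANI is the unweighted mean identity of the
retained fragments.  Two genomes of the same species are expected to show
ANIb >= 95%.

The built-in aligner is a seed-and-extend local search: exact 11-mer seeds
grouped by diagonal, then ungapped X-drop extension.  Gapless high-scoring
segment pairs (HSPs) are exact for substitution-divergence comparisons;
insertions/deletions between genomes simply terminate an HSP and are handled
by the coverage filter.  ``engine="blastn"`` delegates fragment mapping to
NCBI blastn for full-scale replication.

The genome-to-genome distance (dDDH) estimate collects the best HSP per
fragment over the whole genome and computes d = 1 - sum(identities) /
sum(HSP length), mapped to a percent dDDH through a logistic curve whose
coefficients live in config; dDDH >= 70% is the species threshold.
"""

from __future__ import annotations

import math
import shutil
import subprocess
import tempfile
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .config import AniConfig, DdhConfig
from .genome_io import GenomeRecord

_ENC = np.zeros(256, dtype=np.uint8)
for i, c in enumerate("ACGTN"):
    _ENC[ord(c)] = i
N_CODE = 4


def encode(seq: str) -> np.ndarray:
    return _ENC[np.frombuffer(seq.encode(), dtype=np.uint8)]


@dataclass
class Fragment:
    contig_id: str
    start: int
    seq: np.ndarray


@dataclass
class Hsp:
    identity: float        # percent over HSP columns
    length: int            # HSP columns (gapless)
    matches: int
    score: float


@dataclass
class AniResult:
    query_id: str
    subject_id: str
    ani: float | None      # None when no fragment passes the retention filter
    aligned_fraction: float
    n_fragments_used: int
    n_fragments_total: int

    @property
    def defined(self) -> bool:
        return self.ani is not None


def fragment_genome(genome: GenomeRecord, config: AniConfig | None = None) -> list[Fragment]:
    """Cut every contig into consecutive non-overlapping fragments.

    The trailing fragment is kept if it is at least ``min_fragment_len`` nt;
    fragments that are mostly N are dropped.
    """
    config = config or AniConfig()
    if config.fragment_len < 100:
        raise ValueError("fragment_len must be >= 100")
    if genome.length == 0:
        raise ValueError(f"genome {genome.genome_id} is empty")
    frags: list[Fragment] = []
    for cid, seq in genome.contigs:
        enc = encode(seq)
        for start in range(0, len(seq), config.fragment_len):
            piece = enc[start:start + config.fragment_len]
            if piece.size < config.min_fragment_len:
                continue
            if np.mean(piece == N_CODE) > config.max_n_frac:
                continue
            frags.append(Fragment(cid, start, piece))
    return frags


class SubjectIndex:
    """Exact k-mer index over all contigs of the subject genome."""

    def __init__(self, genome: GenomeRecord, config: AniConfig):
        self.config = config
        self.seq = encode(genome.sequence)      # contigs joined; offsets tracked
        self.index: dict[bytes, list[int]] = {}
        k = config.seed_size
        raw = self.seq.tobytes()
        for pos in range(0, len(raw) - k + 1):
            kmer = raw[pos:pos + k]
            if N_CODE in kmer:
                continue
            self.index.setdefault(kmer, []).append(pos)
        # mask out very repetitive seeds
        cap = config.max_seed_hits
        self.index = {k_: v for k_, v in self.index.items() if len(v) <= cap}


def _xdrop_extend(q: np.ndarray, s: np.ndarray, qpos: int, spos: int,
                  config: AniConfig) -> Hsp:
    """Ungapped X-drop extension around a seed on one diagonal."""
    diag = spos - qpos
    lo = max(0, -diag)
    hi = min(q.size, s.size - diag)
    window_q = q[lo:hi]
    window_s = s[lo + diag:hi + diag]
    match = (window_q == window_s) & (window_q != N_CODE)
    score = np.where(match, config.match_score, config.mismatch_score)
    anchor = qpos - lo
    # rightward: cumulative score from the anchor; stop where best-so-far
    # minus running drops below xdrop
    right = np.cumsum(score[anchor:])
    rbest = np.maximum.accumulate(right)
    rstop = np.flatnonzero(rbest - right > config.xdrop)
    rend = int(np.argmax(right[:rstop[0]]) + 1) if rstop.size else int(np.argmax(right) + 1)
    left = np.cumsum(score[:anchor][::-1])
    if left.size:
        lbest = np.maximum.accumulate(left)
        lstop = np.flatnonzero(lbest - left > config.xdrop)
        lend = int(np.argmax(left[:lstop[0]]) + 1) if lstop.size else int(np.argmax(left) + 1)
        if (left[lend - 1]) <= 0:
            lend = 0
    else:
        lend = 0
    if right[rend - 1] <= 0:   # anchor itself scored negative (N run)
        rend = 1
    a, b = anchor - lend, anchor + rend
    m = int(match[a:b].sum())
    length = b - a
    total = float(score[a:b].sum())
    return Hsp(identity=100.0 * m / length, length=length, matches=m, score=total)


def best_fragment_hsp(frag: np.ndarray, subject: SubjectIndex) -> Hsp | None:
    """Best-scoring HSP of one query fragment against the subject genome."""
    config = subject.config
    k = config.seed_size
    raw = frag.tobytes()
    diagonals: dict[int, tuple[int, int]] = {}    # diag -> (count, first qpos)
    step = 4 if frag.size > 200 else 1
    for qpos in range(0, len(raw) - k + 1, step):
        kmer = raw[qpos:qpos + k]
        if N_CODE in kmer:
            continue
        for spos in subject.index.get(kmer, ()):
            d = spos - qpos
            cnt, first = diagonals.get(d, (0, qpos))
            diagonals[d] = (cnt + 1, first)
    if not diagonals:
        return None
    best: Hsp | None = None
    # extend on the few most seed-rich diagonals
    for d, (cnt, qpos) in sorted(diagonals.items(), key=lambda kv: -kv[1][0])[:8]:
        hsp = _xdrop_extend(frag, subject.seq, qpos, qpos + d, config)
        if best is None or hsp.score > best.score:
            best = hsp
    return best


def anib_pair(query: GenomeRecord, subject: GenomeRecord,
              config: AniConfig | None = None,
              subject_index: SubjectIndex | None = None) -> AniResult:
    """One-directional ANIb of ``query`` against ``subject``.

    Returns an explicit undefined result (``ani is None``) when no fragment
    passes the retention filter — never a silent zero.
    """
    config = config or AniConfig()
    if config.engine == "blastn":
        return _anib_pair_blast(query, subject, config)
    frags = fragment_genome(query, config)
    index = subject_index or SubjectIndex(subject, config)
    identities = []
    retained_len = 0
    for frag in frags:
        hsp = best_fragment_hsp(frag.seq, index)
        if hsp is None:
            continue
        if (hsp.identity >= config.min_identity_pct
                and hsp.length >= config.min_alignable_frac * frag.seq.size):
            identities.append(hsp.identity)
            retained_len += hsp.length
    qlen = query.length
    if not identities:
        return AniResult(query.genome_id, subject.genome_id, None, 0.0, 0, len(frags))
    return AniResult(query.genome_id, subject.genome_id,
                     float(np.mean(identities)), retained_len / qlen,
                     len(identities), len(frags))


def _anib_pair_blast(query: GenomeRecord, subject: GenomeRecord,
                     config: AniConfig) -> AniResult:
    """Fragment mapping via NCBI blastn (full-scale replication engine)."""
    if shutil.which("blastn") is None:
        raise RuntimeError("engine='blastn' requires blastn on PATH")
    with tempfile.TemporaryDirectory() as tmp:
        tmp = Path(tmp)
        sub = tmp / "subject.fasta"
        with open(sub, "w") as fh:
            for cid, seq in subject.contigs:
                fh.write(f">{cid}\n{seq}\n")
        frag_file = tmp / "frags.fasta"
        frags = fragment_genome(query, config)
        with open(frag_file, "w") as fh:
            for i, frag in enumerate(frags):
                fh.write(f">f{i}\n{''.join('ACGTN'[b] for b in frag.seq)}\n")
        subprocess.run(["makeblastdb", "-in", str(sub), "-dbtype", "nucl"],
                       check=True, capture_output=True)
        out = subprocess.run(
            ["blastn", "-query", str(frag_file), "-db", str(sub), "-outfmt",
             "6 qseqid pident length nident", "-max_target_seqs", "1",
             "-xdrop_gap", "150", "-penalty", "-1", "-reward", "1", "-dust", "no"],
            check=True, capture_output=True, text=True).stdout
    best: dict[str, tuple[float, int]] = {}
    for line in out.splitlines():
        qid, pident, length, _ = line.split("\t")
        length = int(length)
        if qid not in best or length > best[qid][1]:
            best[qid] = (float(pident), length)
    identities, retained = [], 0
    for i, frag in enumerate(frags):
        hit = best.get(f"f{i}")
        if hit and hit[0] >= config.min_identity_pct \
                and hit[1] >= config.min_alignable_frac * frag.seq.size:
            identities.append(hit[0])
            retained += hit[1]
    if not identities:
        return AniResult(query.genome_id, subject.genome_id, None, 0.0, 0, len(frags))
    return AniResult(query.genome_id, subject.genome_id, float(np.mean(identities)),
                     retained / query.length, len(identities), len(frags))


@dataclass
class AniMatrix:
    """Direction-resolved ANIb values plus the symmetrized view."""

    genomes: list[str]
    directed: pd.DataFrame      # row = query, column = subject; NaN = undefined
    results: dict[tuple[str, str], AniResult]

    @property
    def symmetric(self) -> pd.DataFrame:
        """Mean of the defined directions; diagonal fixed at 100."""
        sym = (self.directed + self.directed.T) / 2.0
        one_way = self.directed.isna() & ~self.directed.T.isna()
        sym = sym.where(~one_way, self.directed.T)
        sym = sym.where(~one_way.T, self.directed)
        np.fill_diagonal(sym.values, 100.0)
        return sym

    def value(self, a: str, b: str) -> float:
        return float(self.symmetric.loc[a, b])

    def to_csv(self, path) -> None:
        self.directed.to_csv(path)

    def to_phylip(self, path) -> None:
        sym = self.symmetric
        with open(path, "w") as fh:
            fh.write(f"{len(self.genomes)}\n")
            for g in self.genomes:
                row = " ".join(f"{sym.loc[g, h]:.4f}" for h in self.genomes)
                fh.write(f"{g}  {row}\n")


def anib_matrix(genomes: list[GenomeRecord],
                config: AniConfig | None = None) -> AniMatrix:
    """Both-direction ANIb for every unordered genome pair."""
    config = config or AniConfig()
    if len(genomes) < 2:
        raise ValueError("need at least two genomes")
    names = [g.genome_id for g in genomes]
    directed = pd.DataFrame(np.nan, index=names, columns=names)
    np.fill_diagonal(directed.values, 100.0)
    indexes = {g.genome_id: SubjectIndex(g, config) if config.engine == "internal" else None
               for g in genomes}
    results = {}
    for i, a in enumerate(genomes):
        for b in genomes[i + 1:]:
            for q, s in ((a, b), (b, a)):
                res = anib_pair(q, s, config, subject_index=indexes[s.genome_id])
                results[(q.genome_id, s.genome_id)] = res
                if res.defined:
                    directed.loc[q.genome_id, s.genome_id] = res.ani
    return AniMatrix(names, directed, results)


@dataclass
class DdhResult:
    query_id: str
    subject_id: str
    d: float | None            # genome-to-genome distance; None when undefined
    ddh: float | None          # percent, via the logistic map
    total_identities: int
    total_hsp_len: int

    @property
    def defined(self) -> bool:
        return self.d is not None


def gg_distance(total_identities: int, total_hsp_len: int) -> float:
    """Genome-to-genome distance: 1 - summed identities / summed HSP length."""
    if total_hsp_len <= 0:
        raise ValueError("total HSP length must be positive")
    return 1.0 - total_identities / total_hsp_len


def ddh_from_distance(d: float, config: DdhConfig | None = None) -> float:
    """Map a genome-to-genome distance to percent dDDH via the logistic curve."""
    config = config or DdhConfig()
    return 100.0 / (1.0 + math.exp(config.logistic_a + config.logistic_b * d))


def ddh_pair(a: GenomeRecord, b: GenomeRecord,
             ani_config: AniConfig | None = None,
             ddh_config: DdhConfig | None = None) -> DdhResult:
    """GGDC-style dDDH: d = 1 - sum(identities)/sum(HSP length) over all HSPs."""
    ani_config = ani_config or AniConfig()
    ddh_config = ddh_config or DdhConfig()
    if a.length == 0 or b.length == 0:
        raise ValueError("both genomes must be non-empty")
    index = SubjectIndex(b, ani_config)
    total_matches = 0
    total_len = 0
    for frag in fragment_genome(a, ani_config):
        hsp = best_fragment_hsp(frag.seq, index)
        if hsp is None or hsp.length < ddh_config.min_hsp_len:
            continue
        total_matches += hsp.matches
        total_len += hsp.length
    if total_len == 0:
        return DdhResult(a.genome_id, b.genome_id, None, None, 0, 0)
    d = gg_distance(total_matches, total_len)
    return DdhResult(a.genome_id, b.genome_id, d, ddh_from_distance(d, ddh_config),
                     total_matches, total_len)
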