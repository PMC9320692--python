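"""Genome and gene I/O, ORF extraction and per-genome summary statistics.

Conventions used throughout the package:

* one nucleotide multi-FASTA per strain; the genome identifier defaults to
  the file stem and must be unique within a run;
* gene coordinates are 0-based half-open on the contig; strand ``-`` means
  the protein is translated from the reverse complement of the slice;
* proteins are translated with the bacterial genetic code (NCBI table 11)
  and a terminal stop codon is stripped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

VALID_CHARS = set("ACGTN")
START_CODONS = ("ATG", "GTG", "TTG")
STOP_CODONS = ("TAA", "TAG", "TGA")


@dataclass
class GenomeRecord:
    """Contigs plus metadata for one strain."""

    genome_id: str
    contigs: list[tuple[str, str]]
    source: str = ""

    def __post_init__(self) -> None:
        if not self.contigs or any(not seq for _, seq in self.contigs):
            raise ValueError(f"genome {self.genome_id!r}: every contig must be non-empty")

    @property
    def length(self) -> int:
        return sum(len(seq) for _, seq in self.contigs)

    def contig(self, contig_id: str) -> str:
        for cid, seq in self.contigs:
            if cid == contig_id:
                return seq
        raise KeyError(contig_id)

    @property
    def sequence(self) -> str:
        """All contigs joined; used for whole-genome statistics only."""
        return "".join(seq for _, seq in self.contigs)


@dataclass
class GeneRecord:
    """One protein-coding gene located on a contig."""

    gene_id: str
    genome_id: str
    contig_id: str
    start: int
    end: int
    strand: str
    protein: str = ""

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"gene {self.gene_id}: bad interval [{self.start},{self.end})")
        if self.strand not in "+-":
            raise ValueError(f"gene {self.gene_id}: strand must be '+' or '-'")


def _clean(seq: str, label: str) -> str:
    seq = seq.upper()
    bad = sum(1 for c in seq if c not in VALID_CHARS)
    if bad:
        logger.info("%s: replaced %d non-ACGTN characters with N", label, bad)
        seq = "".join(c if c in VALID_CHARS else "N" for c in seq)
    return seq


def read_genomes(paths: Sequence[str | Path], ids: Sequence[str] | None = None) -> list[GenomeRecord]:
    """Read one multi-FASTA per strain into :class:`GenomeRecord` objects.

    ``ids`` overrides the default genome identifiers (the file stems).
    Characters outside {A,C,G,T,N} are replaced by N with a logged count.
    """
    genomes: list[GenomeRecord] = []
    seen: set[str] = set()
    for i, path in enumerate(paths):
        path = Path(path)
        gid = ids[i] if ids is not None else path.stem
        if gid in seen:
            raise ValueError(f"duplicate genome_id {gid!r} (from {path})")
        seen.add(gid)
        contigs = [(rec.id, _clean(str(rec.seq), f"{gid}/{rec.id}"))
                   for rec in SeqIO.parse(str(path), "fasta")]
        if not contigs:
            raise ValueError(f"no FASTA records in {path}")
        genomes.append(GenomeRecord(genome_id=gid, contigs=contigs, source=str(path)))
    return genomes


def write_genome(genome: GenomeRecord, path: str | Path) -> None:
    records = [SeqRecord(Seq(seq), id=cid, description="") for cid, seq in genome.contigs]
    SeqIO.write(records, str(path), "fasta")


def gc_content(genome: GenomeRecord) -> float:
    """G+C percentage of the assembly, N excluded from the denominator.

    Computed directly from the genome sequence and reported to 0.1%.
    """
    seq = genome.sequence
    counts = {c: seq.count(c) for c in "ACGT"}
    denom = sum(counts.values())
    if denom == 0:
        raise ValueError(f"genome {genome.genome_id}: no non-N bases, GC undefined")
    return round(100.0 * (counts["G"] + counts["C"]) / denom, 1)


def translate_cds(nt: str) -> str:
    """Translate a CDS with translation table 11, stripping a terminal stop."""
    prot = str(Seq(nt[: len(nt) - len(nt) % 3]).translate(table=11))
    if prot.endswith("*"):
        prot = prot[:-1]
    return prot


def _revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def extract_genes(
    genome: GenomeRecord,
    annotation: Iterable[GeneRecord] | None = None,
    min_orf_len: int = 90,
) -> list[GeneRecord]:
    """Extract protein-coding genes from a genome.

    With an annotation (a CDS coordinate table) the listed intervals are
    translated directly; an annotated CDS containing an internal stop codon
    is skipped with a warning.  Without one, a dependency-free ORF caller is
    used: per frame and strand, the longest ATG/GTG/TTG-to-stop open reading
    frame of at least ``min_orf_len`` nt; overlapping calls on the same
    strand are resolved by length then leftmost start.
    """
    if annotation is not None:
        out = []
        for gene in annotation:
            contig = genome.contig(gene.contig_id)
            if gene.end > len(contig):
                raise ValueError(f"gene {gene.gene_id}: end {gene.end} beyond contig")
            nt = contig[gene.start:gene.end]
            if gene.strand == "-":
                nt = _revcomp(nt)
            prot = translate_cds(nt)
            if "*" in prot:
                logger.warning("gene %s: internal stop codon, skipped", gene.gene_id)
                continue
            if not prot:
                continue
            out.append(GeneRecord(gene.gene_id, genome.genome_id, gene.contig_id,
                                  gene.start, gene.end, gene.strand, prot))
        return out
    return _call_orfs(genome, min_orf_len)


def _orfs_on_strand(seq: str, min_len: int) -> list[tuple[int, int]]:
    """All maximal start-to-stop ORFs (forward coordinates on ``seq``)."""
    n = len(seq)
    orfs = []
    for frame in range(3):
        start = None
        for pos in range(frame, n - 2, 3):
            codon = seq[pos:pos + 3]
            if start is None and codon in START_CODONS:
                start = pos
            elif start is not None and codon in STOP_CODONS:
                if pos + 3 - start >= min_len:
                    orfs.append((start, pos + 3))
                start = None
    return orfs


def _call_orfs(genome: GenomeRecord, min_len: int) -> list[GeneRecord]:
    genes: list[GeneRecord] = []
    counter = 0
    for cid, seq in genome.contigs:
        calls: list[tuple[int, int, str]] = []
        for start, end in _orfs_on_strand(seq, min_len):
            calls.append((start, end, "+"))
        rc = _revcomp(seq)
        for start, end in _orfs_on_strand(rc, min_len):
            calls.append((len(seq) - end, len(seq) - start, "-"))
        # greedy resolution of overlaps: longest first, then leftmost start
        calls.sort(key=lambda c: (-(c[1] - c[0]), c[0]))
        taken: list[tuple[int, int]] = []
        for start, end, strand in calls:
            if any(start < e and s < end for s, e in taken):
                continue
            taken.append((start, end))
            nt = seq[start:end] if strand == "+" else _revcomp(seq[start:end])
            prot = translate_cds(nt)
            if "*" in prot or not prot:
                continue
            counter += 1
            genes.append(GeneRecord(f"{genome.genome_id}_orf{counter:05d}",
                                    genome.genome_id, cid, start, end, strand, prot))
    genes.sort(key=lambda g: (g.contig_id, g.start))
    return genes


GENE_TABLE_COLUMNS = ["gene_id", "genome_id", "contig_id", "start", "end", "strand"]


def write_gene_table(genes: Iterable[GeneRecord], path: str | Path) -> None:
    """Write genes as a tab-separated coordinate table (GFF3-derived export)."""
    with open(path, "w") as fh:
        fh.write("\t".join(GENE_TABLE_COLUMNS) + "\n")
        for g in genes:
            fh.write(f"{g.gene_id}\t{g.genome_id}\t{g.contig_id}\t{g.start}\t{g.end}\t{g.strand}\n")


def read_gene_table(path: str | Path) -> list[GeneRecord]:
    genes = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != GENE_TABLE_COLUMNS:
            raise ValueError(f"unexpected gene-table header in {path}")
        for line in fh:
            gene_id, genome_id, contig_id, start, end, strand = line.rstrip("\n").split("\t")
            genes.append(GeneRecord(gene_id, genome_id, contig_id, int(start), int(end), strand))
    return genes


def write_proteins(genes: Iterable[GeneRecord], path: str | Path) -> None:
    records = [SeqRecord(Seq(g.protein), id=g.gene_id, description=g.genome_id)
               for g in genes if g.protein]
    SeqIO.write(records, str(path), "fasta")
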