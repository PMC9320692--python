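"""Configuration objects for every pipeline stage.

All thresholds that the taxonomy hinges on (ANIb 95%, dDDH 70%, ortholog
identity 70%, e-value 0.01) live here as data, never as literals buried in
code, so a run manifest can record exactly what was used.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml


@dataclass
class OrthologyConfig:
    identity_min: float = 70.0          # percent; the study's working threshold
    evalue_max: float = 0.01
    kmer_size: int = 5
    kmer_min_shared: int = 3
    use_prefilter: bool = True
    gap_open: float = -11.0
    gap_extend: float = -1.0
    matrix: str = "BLOSUM62"


@dataclass
class AniConfig:
    fragment_len: int = 1020            # JSpecies/Goris fragment size, nt
    min_fragment_len: int = 100         # trailing fragments below this are dropped
    min_identity_pct: float = 30.0      # fragment retention filter
    min_alignable_frac: float = 0.70
    max_n_frac: float = 0.50            # fragments with more N than this are dropped
    seed_size: int = 11
    xdrop: float = 30.0
    match_score: float = 1.0
    mismatch_score: float = -2.0
    max_seed_hits: int = 50             # k-mers occurring more often are skipped
    symmetrization: str = "mean"
    engine: str = "internal"            # or "blastn" for full-scale replication


@dataclass
class DdhConfig:
    # dDDH = 100 / (1 + exp(a + b * d)); anchored so ddh(0) = 99.9 and
    # ddh(d70) = 70 exactly at the conventional species boundary distance.
    d70: float = 0.0336
    logistic_a: float = -6.906755
    logistic_b: float = 180.3273
    min_hsp_len: int = 100


@dataclass
class PhylogenyConfig:
    method: str = "nj"                  # or "ml_poisson" (small taxon sets)
    ml_max_taxa: int = 15
    bootstrap_replicates: int = 100
    outgroup: list[str] = field(default_factory=list)


@dataclass
class DelineationConfig:
    ani_threshold: float = 95.0
    ddh_threshold: float = 70.0
    borderline_delta: float = 1.0       # percentage points below ani_threshold
    discontinuity_gap: float = 2.0      # min intra ANI minus max outside ANI
    use_rescue: bool = True             # disable for a pure threshold+monophyly rule


@dataclass
class SimConfig:
    seed: int = 0
    n_species: int = 3
    strains_per_species: int = 4
    n_genes: int = 300
    gene_len: int = 900                 # nt, multiple of 3, includes start+stop
    intergenic_len: int = 120
    within_divergence: float = 0.01     # expected per-site substitution fraction
    between_divergence: float = 0.10
    gene_loss_rate: float = 1.5         # expected loss events per branch
    gene_gain_rate: float = 1.0         # expected novel-gene gains per branch
    n_contigs: int = 3
    gc: float = 0.60
    hgt_rate: float = 0.0               # optional cross-lineage gene copying

    def __post_init__(self) -> None:
        if not (0 <= self.within_divergence < 0.75
                and 0 <= self.between_divergence < 0.75):
            raise ValueError("divergences must lie in [0, 0.75)")
        if self.gene_loss_rate < 0 or self.gene_gain_rate < 0:
            raise ValueError("gain/loss rates must be >= 0")
        if self.gene_len % 3:
            raise ValueError("gene_len must be a multiple of 3")


@dataclass
class PipelineConfig:
    genomes: list[str] = field(default_factory=list)
    annotations: list[str] = field(default_factory=list)
    outdir: str = "genotax_out"
    min_orf_len: int = 90
    orthology: OrthologyConfig = field(default_factory=OrthologyConfig)
    ani: AniConfig = field(default_factory=AniConfig)
    ddh: DdhConfig = field(default_factory=DdhConfig)
    phylogeny: PhylogenyConfig = field(default_factory=PhylogenyConfig)
    delineation: DelineationConfig = field(default_factory=DelineationConfig)
    simulate: SimConfig | None = None
    compute_ddh: bool = False

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)


_SECTIONS = {
    "orthology": OrthologyConfig,
    "ani": AniConfig,
    "ddh": DdhConfig,
    "phylogeny": PhylogenyConfig,
    "delineation": DelineationConfig,
    "simulate": SimConfig,
}


def load_config(path: str | Path) -> PipelineConfig:
    """Load a pipeline configuration from a YAML file."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    return config_from_dict(raw)


def config_from_dict(raw: dict[str, Any]) -> PipelineConfig:
    kwargs: dict[str, Any] = {}
    for key, value in raw.items():
        if key in _SECTIONS:
            if value is None:
                value = {}
            kwargs[key] = _SECTIONS[key](**value)
        else:
            kwargs[key] = value
    return PipelineConfig(**kwargs)
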