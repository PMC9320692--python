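# Methods

This note documents the models and procedures implemented in `genotax`,
the parameters that matter, the numerical choices made where conventions
diverge, what the synthetic-data generator does and does not emulate, and
the known limitations.

## Species concept and delineation rule

The operational unit is the *phylogenomic species* (pgs): a clade of the
core-genome tree whose members all share genomic indices at or above the
species thresholds. Defaults (all in `DelineationConfig`):

| parameter | default | meaning |
|---|---|---|
| `ani_threshold` | 95.0 % | minimum intra-clade symmetrized ANIb |
| `ddh_threshold` | 70.0 % | dDDH alternative for borderline rescue |
| `borderline_delta` | 1.0 point | how far below `ani_threshold` a clade may fall and still be considered |
| `discontinuity_gap` | 2.0 points | required gap between min intra ANI and the nearest outside genome |
| `use_rescue` | true | disable for a pure threshold+monophyly rule |

The scan enumerates every clade of the unrooted tree (both sides of every
bipartition, largest first) and greedily accepts clades passing the rule;
accepted clades are bipartition-disjoint by construction, and leftovers
become singletons. The borderline rescue encodes the practice of keeping a
tight, clearly isolated cluster together even when its lowest intra pair
dips just under the cutoff: "borderline" is operationalized as at most
`borderline_delta` below threshold, and "clear discontinuity" as a gap of
at least `discontinuity_gap` points to the nearest non-member. Both are
config, not code; the defaults admit the canonical borderline case (min
intra 94.2, nearest outsider 92, gap 2.2). Tests demonstrate the rule is
load-bearing: with the rescue disabled the same fixture shatters into
singletons.

Cluster numbering is stable: seeded labels (e.g. reference strains) win,
then decreasing cluster size, then the lexicographically smallest member.

## ANIb

JSpecies/Goris-style: consecutive non-overlapping 1020-nt fragments per
contig (trailing fragment kept at ≥ 100 nt; fragments > 50% N dropped);
each fragment's best local alignment against the subject; retained iff
identity ≥ 30% over an alignable region ≥ 70% of the fragment; ANI =
unweighted mean identity of retained fragments. Both directions are always
computed; the symmetric view is the mean of the defined directions (if only
one direction is defined it is used as-is). An undefined ANI (no retained
fragment) is an explicit flagged result, never a silent 0.

The built-in aligner is seed-and-extend: exact 11-mer seeds (k-mers with
more than 50 subject positions are masked as repetitive), seeds grouped by
diagonal, ungapped X-drop extension (match +1, mismatch −2, X-drop 30) on
the most seed-rich diagonals. Gapless HSPs are exact for
substitution-divergence comparisons; an insertion/deletion between the
genomes simply terminates the HSP and the coverage filter handles the
remainder. A consequence of the +1/−2 scoring worth noting: any
positive-scoring segment has identity ≥ 2/3, which is why unrelated genomes
can never produce a retained fragment. Subject contigs are indexed as one
concatenated sequence; an HSP could in principle bridge two contigs, a
negligible desk-scale artifact since extensions die at the X-drop within a
few dozen bases of non-homology. `engine="blastn"` delegates fragment
mapping to NCBI blastn for full-scale replication; all tests run on the
internal engine.

On simulated data the measured ANIb tracks the truth (100 × (1 − realized
substitution fraction over shared sites)) to within ~0.12 points at the
default study's divergences; the test suite enforces ≤ 0.5.

## dDDH

Genome-to-genome distance d = 1 − Σidentities/ΣHSP-length over the best
HSP per 1020-nt fragment (HSPs shorter than 100 nt ignored), mapped to a
percentage by the logistic curve ddh = 100/(1+exp(a + b·d)). The
coefficients are configuration data anchored so that ddh(0) = 99.9 and
ddh = 70 exactly at d = 0.0336, the conventional species-boundary distance
for the identities/HSP-length formula; with them, "ddh ≥ 70" and
"d ≤ d70" are the same predicate by construction. Pairs with no HSPs give
an explicit undefined result.

## Orthology

Local protein alignment with BLOSUM62, gap open −11 / extend −1, for every
cross-genome pair passing a shared-k-mer prefilter (≥ 3 shared 5-mers by
default; ~0% of unrelated pairs pass, homologs at ≥ 50% identity share
dozens). The prefilter can be disabled (`use_prefilter=False`) for
exhaustive oracle comparisons. E-values use the extreme-value form
E = K·m·n·exp(−λS) with λ and K fitted once per run by method-of-moments on
scores of shuffled decoy pairs — same cutoff semantics as a database
search without claiming bit-compatibility with any engine. Hits are kept at
identity ≥ `identity_min` (70% working default; 50/60/70/80 supported) and
E ≤ 0.01. Identity counts identical positions over aligned columns
including internal gaps.

RBH ties are broken by higher identity then lexicographic gene id. Ortholog
groups are connected components of the pooled RBH graph (the loosest
published convention; stricter clique-like clustering is out of scope).
Core genes require presence in every genome *and* single-copy in every
genome — multi-copy universal groups are excluded (and logged) because the
downstream concatenation needs exactly one sequence per genome.

## Phylogeny

Family alignment is delegated to MAFFT (`--auto`, deterministic for fixed
input order); blocks are concatenated in sorted group-id order with
partition spans recorded. Distances are Poisson-corrected p-distances with
pairwise gap deletion; p ≥ 1 is capped with a warning. Default inference is
neighbor joining (negative branch lengths clamped to 0). For ≤ 15 taxa a
Poisson-model (equal rates, equal frequencies, 20 states) maximum-
likelihood search is available: exhaustive topology enumeration up to 6
taxa, NNI hill-climbing from the NJ tree above that, branch lengths by
L-BFGS-B on the pruning likelihood with site-pattern compression. The
rationale for distance-based default inference: the tree's downstream use
is branching order and monophyly of candidate species, which strong
desk-scale signal determines identically under NJ and ML.

Bootstrap resamples columns of the concatenated alignment with replacement,
ignoring partition boundaries (the simplest published convention), per
replicate; support of each point-tree bipartition is the percentage of
replicates containing it. All resampling flows from one seed. Monophyly of
a leaf set means a single edge of the unrooted tree separates exactly that
set; singleton and full sets are trivially monophyletic. Rooting by a named
outgroup is a config option; trees are otherwise treated as unrooted.

## Phyletic pattern

Jaccard similarity of presence/absence rows. Two modes: `standard`
a/(a+b+c) (default) and `paper` a/(a+b+c+d), which counts genes absent from
both genomes in the denominator. The second form makes the denominator the
constant total group count, so it ranks pairs exactly as the shared count
*a* does; it is preserved because it is the printed convention in part of
the literature, but the standard form is the default. Clustering uses
distance 1 − s and an in-repo UPGMA with a deterministic tie-break
(smallest lexicographic pair); merge heights are recorded as d/2
(ultrametric node heights). NEXUS exports (distance block or binary
characters block) feed splits-network viewers; the network computation
itself is external by design.

## Synthetic-data generator

What it emulates: a clade of bacterial genomes with known tree, known
pairwise divergence (hence known true ANI), and known gene content.

* **Tree.** Pure-birth species topology; strain subtrees are stars attached
  at height t_w/2; species splits at t_b/2 up to 1.3·t_b/2, where
  t(p) = −(3/4)ln(1 − 4p/3) converts a target observed divergence into
  Jukes–Cantor path time. Within pairs therefore show exactly
  `within_divergence` expected substitutions per site and every between
  pair at least `between_divergence`.
* **Sequence.** Ancestor of `n_genes` genes (ATG + random non-stop codons +
  TAA, GC-biased, default 60%) separated by 120-nt spacers. Substitutions
  are i.i.d. Jukes–Cantor events per branch with codon-position rate
  weights 0.6/0.6/1.8 (mean 1), so proteins diverge more slowly than
  nucleotides; a substitution that would create an in-frame stop is redrawn
  among non-stop bases, keeping every annotated CDS a clean ORF (the
  first-order rate correction for this is folded into the stored per-pair
  expectations, which the realized fractions match within 3 standard
  errors). No rate heterogeneity across sites beyond the codon weights.
* **Gene turnover.** Poisson loss events per branch delete the gene's DNA;
  gains insert novel random-sequence genes with no homology to anything
  (so orthology cannot cross-link them). An optional HGT mode copies an
  evolved gene between lineages instead, creating phyletic discordance;
  events are recorded in the truth.
* **Emission.** Each genome is split into `n_contigs` contigs at intergenic
  points; gained genes are appended to the last contig. All genes sit on
  the '+' strand. Truth tables include the true tree (newick), the species
  partition, realized and expected per-pair substitution fractions (over
  ancestral positions retained in both genomes; shared gained genes are
  excluded from this bookkeeping), the presence/absence table, and
  per-family protein sets.

What it does not emulate — and hence what passing tests do not show about
real data: intra-gene indels, rearrangements, rate heterogeneity and
selection beyond the codon weights, compositional heterogeneity,
contamination or assembly error, paralogous families, and pseudogenes.
Recovery of the true partition on this generator validates the machinery
and the rule, not the hard cases of real taxonomy (recombination,
uneven sampling, MAG incompleteness).

## Study sizes and determinism

The default validation study is 3 species × 4 strains, 300 genes of 900 nt
(~300 kb genomes), within-divergence 0.01, between 0.10, 100 bootstrap
replicates — large enough that bootstrap support of true clades is 100%
and ANI error ≤ 0.5 points, small enough to run in a few minutes on one
CPU. All randomness (simulation, bootstrap, decoy fitting) flows from
explicit seeds; two runs with the same seed and config produce
bit-identical outputs, which the run manifest's checksums make checkable.

## Known limitations

* The ML search is desk-scale only (≤ 15 taxa) and uses the Poisson model;
  large trees use NJ.
* The internal nucleotide aligner is gapless; genomes with many small
  indels between homologs will lose fragments to the coverage filter
  sooner than a gapped aligner would (the blastn engine covers that case).
* E-value calibration is per-run and dataset-dependent; e-values are
  comparable within a run, not across engines.
* Connected-component orthology can chain families through promiscuous
  hits in principle; the identity floor makes this rare but it is the
  known failure mode of the convention.
* The UPGMA implementation is O(n³) — fine for hundreds of genomes, not
  tens of thousands.
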