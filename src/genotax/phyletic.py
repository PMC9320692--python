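"""Gene-content similarity, UPGMA dendrogram, and splits-network export.

The phyletic pattern (presence/absence of every ortholog group per genome)
carries a taxonomic signal of its own: strains of the same species share
most of their gene content.  Pairwise similarity uses the Jaccard index.
Two variants are exposed:

* ``standard`` (default): a / (a + b + c) — shared genes over genes present
  in at least one of the pair;
* ``paper``: a / (a + b + c + d), which also counts the genes absent from
  both genomes, making the denominator the constant total group count; the
  induced ranking of pairs then equals ranking by the shared count a.

Here a = groups present in both genomes, b and c = present in exactly one,
d = absent from both.  Clustering converts similarity to distance 1 - s and
applies UPGMA (average linkage) with a deterministic tie-break (smallest
lexicographic pair).  A NEXUS export (distance or binary-character block)
feeds splits-network viewers; the network computation itself is external.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


def pair_counts(x, y) -> tuple[int, int, int, int]:
    """(a, b, c, d) presence/absence counts for two 0/1 pattern rows."""
    x = np.asarray(x, dtype=bool)
    y = np.asarray(y, dtype=bool)
    if x.shape != y.shape:
        raise ValueError("pattern rows must cover the same group universe")
    a = int(np.sum(x & y))
    b = int(np.sum(x & ~y))
    c = int(np.sum(~x & y))
    d = int(np.sum(~x & ~y))
    return a, b, c, d


def pair_similarity(x, y, mode: str = "standard") -> float:
    """Jaccard similarity of two phyletic pattern rows.

    Raises on an all-absent pair in standard mode (undefined), never
    returning a silent value.
    """
    a, b, c, d = pair_counts(x, y)
    if mode == "paper":
        return a / (a + b + c + d)
    if mode == "standard":
        if a + b + c == 0:
            raise ValueError("similarity undefined: no group present in either genome")
        return a / (a + b + c)
    raise ValueError(f"unknown mode {mode!r}")


def similarity_matrix(pattern: pd.DataFrame, mode: str = "standard") -> pd.DataFrame:
    """Pairwise Jaccard similarity over the rows of a genomes-x-groups table."""
    genomes = list(pattern.index)
    values = pattern.values.astype(bool)
    n = len(genomes)
    sim = np.ones((n, n)) if mode == "standard" else np.empty((n, n))
    for i in range(n):
        for j in range(i, n):
            s = pair_similarity(values[i], values[j], mode=mode)
            sim[i, j] = sim[j, i] = s
    return pd.DataFrame(sim, index=genomes, columns=genomes)


@dataclass
class Dendrogram:
    """Ultrametric average-linkage tree with recorded merge heights."""

    merges: list[tuple[frozenset[str], frozenset[str], float]]   # height = d/2
    leaves: list[str]

    @property
    def heights(self) -> list[float]:
        """Ultrametric merge heights (half the average linkage distance)."""
        return [h for _, _, h in self.merges]

    def newick(self) -> str:
        node_of: dict[frozenset[str], str] = {
            frozenset([leaf]): leaf for leaf in self.leaves}
        height_of: dict[frozenset[str], float] = {
            frozenset([leaf]): 0.0 for leaf in self.leaves}
        for left, right, h in self.merges:
            ln = f"{node_of[left]}:{h - height_of[left]:.6g}"
            rn = f"{node_of[right]}:{h - height_of[right]:.6g}"
            merged = left | right
            node_of[merged] = f"({ln},{rn})"
            height_of[merged] = h
        return node_of[frozenset(self.leaves)] + ";"

    def clusters_at(self, height: float) -> list[frozenset[str]]:
        """Flat clusters obtained by cutting the dendrogram at a height."""
        clusters = {frozenset([leaf]) for leaf in self.leaves}
        for left, right, h in self.merges:
            if h <= height:
                clusters -= {left, right}
                clusters.add(left | right)
        return sorted(clusters, key=lambda s: sorted(s))


def upgma(dist: pd.DataFrame) -> Dendrogram:
    """Average-linkage agglomeration of a symmetric distance matrix.

    Ties on the minimum distance are broken by the smallest lexicographic
    pair of cluster representatives; merge heights are non-decreasing.
    """
    values = dist.values.astype(float)
    if values.shape[0] != values.shape[1] or not np.allclose(values, values.T):
        raise ValueError("UPGMA requires a symmetric distance matrix")
    if np.any(values < -1e-12):
        raise ValueError("distances must be >= 0")
    names = list(dist.index)
    clusters: dict[frozenset[str], list[int]] = {
        frozenset([nm]): [i] for i, nm in enumerate(names)}
    merges: list[tuple[frozenset[str], frozenset[str], float]] = []
    while len(clusters) > 1:
        best = None
        for ca in clusters:
            for cb in clusters:
                if min(ca) >= min(cb):
                    continue
                members_a, members_b = clusters[ca], clusters[cb]
                d = float(np.mean(values[np.ix_(members_a, members_b)]))
                key = (d, min(ca), min(cb))
                if best is None or key < best[0]:
                    best = (key, ca, cb)
        (d, _, _), ca, cb = best
        merges.append((ca, cb, d / 2.0))
        clusters[ca | cb] = clusters.pop(ca) + clusters.pop(cb)
    return Dendrogram(merges, names)


def _nexus_label(label: str) -> str:
    if any(ch in label for ch in " ()[]{}/\\,;:=*'\"`<>^"):
        return "'" + label.replace("'", "''") + "'"
    return label


def export_splits_distances(dist: pd.DataFrame) -> str:
    """NEXUS text with a Taxa and a Distances block for splits software."""
    names = list(dist.index)
    if len(names) < 4:
        raise ValueError("splits export needs at least 4 genomes")
    lines = ["#NEXUS", "", "BEGIN Taxa;", f"DIMENSIONS ntax={len(names)};",
             "TAXLABELS"]
    lines += [f"    [{i + 1}] {_nexus_label(nm)}" for i, nm in enumerate(names)]
    lines += [";", "END;", "", "BEGIN Distances;",
              f"DIMENSIONS ntax={len(names)};",
              "FORMAT labels=left diagonal triangle=both;", "MATRIX"]
    for nm in names:
        row = " ".join(f"{dist.loc[nm, other]:.6f}" for other in names)
        lines.append(f"    {_nexus_label(nm)} {row}")
    lines += [";", "END;", ""]
    return "\n".join(lines)


def export_splits_characters(pattern: pd.DataFrame) -> str:
    """NEXUS text with the binary phyletic pattern as a Characters block."""
    names = list(pattern.index)
    if len(names) < 4:
        raise ValueError("splits export needs at least 4 genomes")
    nchar = pattern.shape[1]
    lines = ["#NEXUS", "", "BEGIN Taxa;", f"DIMENSIONS ntax={len(names)};",
             "TAXLABELS"]
    lines += [f"    [{i + 1}] {_nexus_label(nm)}" for i, nm in enumerate(names)]
    lines += [";", "END;", "", "BEGIN Characters;",
              f"DIMENSIONS nchar={nchar};",
              'FORMAT datatype=standard symbols="01";', "MATRIX"]
    for nm in names:
        lines.append(f"    {_nexus_label(nm)} {''.join(map(str, pattern.loc[nm]))}")
    lines += [";", "END;", ""]
    return "\n".join(lines)


def parse_nexus_taxa(text: str) -> list[str]:
    """Labels from the TAXLABELS section of our own NEXUS export (round-trip
    check helper)."""
    labels = []
    in_block = False
    for line in text.splitlines():
        s = line.strip()
        if s == "TAXLABELS":
            in_block = True
            continue
        if in_block:
            if s == ";":
                break
            label = s.split("] ", 1)[1]
            if label.startswith("'"):
                label = label[1:-1].replace("''", "'")
            labels.append(label)
    return labels
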