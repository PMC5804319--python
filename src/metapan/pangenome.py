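"""Pangenome layer: occurrence matrix, bins, dendrograms, annotation rates.

Gene clusters are tabulated across genomes (counts and presence), assigned
to five occurrence bins (core to all genomes, core to the high-light or
low-light clade, singleton, other), and both genomes and gene clusters are
ordered by agglomerative Ward clustering on Euclidean distances between
presence vectors.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.cluster.hierarchy import linkage

from .model import (
    AnnotationRecord,
    BinAssignment,
    Dendrogram,
    GeneCluster,
    Genome,
    MetapanError,
    PangenomeBin,
)

__all__ = [
    "BinAssignment",
    "Dendrogram",
    "OccurrenceMatrix",
    "PangenomeBin",
    "build_occurrence",
    "assign_bins",
    "cluster_genomes",
    "cluster_gene_clusters",
    "annotation_rate",
    "write_occurrence_tsv",
    "write_bins_tsv",
    "read_bins_tsv",
]


@dataclass
class OccurrenceMatrix:
    """Gene-cluster x genome gene counts (rows sorted by cluster id)."""

    cluster_ids: list[str]
    genome_ids: list[str]
    counts: np.ndarray  # int, shape (n_clusters, n_genomes)

    def __post_init__(self) -> None:
        if self.counts.shape != (len(self.cluster_ids), len(self.genome_ids)):
            raise MetapanError("occurrence matrix shape mismatch")
        if np.any(self.counts < 0):
            raise MetapanError("negative occurrence count")

    @property
    def presence(self) -> np.ndarray:
        return self.counts > 0

    def genomes_present(self, cluster_id: str) -> int:
        i = self.cluster_ids.index(cluster_id)
        return int(self.presence[i].sum())


def build_occurrence(
    clusters: list[GeneCluster], genomes: list[Genome]
) -> OccurrenceMatrix:
    """Count genes contributed by each genome to each cluster.

    Also fills each cluster's ``genome_multiplicity`` in place. A gene that
    belongs to no known genome is fatal.
    """
    gene_to_genome = {
        g.gene_id: genome.genome_id for genome in genomes for g in genome.genes
    }
    cluster_ids = sorted(c.cluster_id for c in clusters)
    if len(set(cluster_ids)) != len(cluster_ids):
        raise MetapanError("duplicate cluster ids")
    genome_ids = sorted(g.genome_id for g in genomes)
    ci = {c: i for i, c in enumerate(cluster_ids)}
    gi = {g: i for i, g in enumerate(genome_ids)}

    counts = np.zeros((len(cluster_ids), len(genome_ids)), dtype=int)
    for c in sorted(clusters, key=lambda c: c.cluster_id):
        mult: dict[str, int] = {}
        for gid in c.member_gene_ids:
            if gid not in gene_to_genome:
                raise MetapanError(f"gene {gid!r} in cluster {c.cluster_id} "
                                   "belongs to no known genome")
            genome_id = gene_to_genome[gid]
            mult[genome_id] = mult.get(genome_id, 0) + 1
            counts[ci[c.cluster_id], gi[genome_id]] += 1
        c.genome_multiplicity = mult
    return OccurrenceMatrix(cluster_ids=cluster_ids, genome_ids=genome_ids,
                            counts=counts)


def assign_bins(
    occ: OccurrenceMatrix, light_class: dict[str, str]
) -> list[BinAssignment]:
    """Assign each cluster to one of the five occurrence bins.

    Precedence: CORE_ALL (present in every genome) > SINGLETON (present in
    exactly one genome) > CORE_HL / CORE_LL (present in every genome of
    that light class, in none of the others, and only when the complement
    class is non-empty) > OTHER. With a single genome every cluster is a
    SINGLETON, not CORE_ALL.
    """
    if not occ.genome_ids:
        raise MetapanError("empty genome set")
    missing = [g for g in occ.genome_ids if g not in light_class]
    if missing:
        raise MetapanError(f"no light class for genomes {missing[:10]}")

    hl = np.array([light_class[g] == "HL" for g in occ.genome_ids])
    ll = np.array([light_class[g] == "LL" for g in occ.genome_ids])
    presence = occ.presence
    out: list[BinAssignment] = []
    for i, cid in enumerate(occ.cluster_ids):
        row = presence[i]
        n_present = int(row.sum())
        if n_present == 0:
            raise MetapanError(f"cluster {cid} present in no genome")
        if n_present == len(occ.genome_ids) and n_present > 1:
            b = PangenomeBin.CORE_ALL
        elif n_present == 1:
            b = PangenomeBin.SINGLETON
        elif hl.any() and ll.any() and row[hl].all() and not row[~hl].any():
            b = PangenomeBin.CORE_HL
        elif hl.any() and ll.any() and row[ll].all() and not row[~ll].any():
            b = PangenomeBin.CORE_LL
        else:
            b = PangenomeBin.OTHER
        out.append(BinAssignment(cluster_id=cid, bin=b))
    return out


def _ward(vectors: np.ndarray, labels: list[str]) -> Dendrogram:
    if len(labels) < 2:
        raise MetapanError("hierarchical clustering needs >= 2 items")
    order = np.argsort(np.array(labels, dtype=object))
    sorted_labels = [labels[i] for i in order]
    Z = linkage(vectors[order].astype(float), method="ward", metric="euclidean")
    return Dendrogram(linkage=Z, labels=sorted_labels, method="ward",
                      metric="euclidean")


def cluster_genomes(occ: OccurrenceMatrix, use_counts: bool = False) -> Dendrogram:
    """Ward/Euclidean dendrogram of genomes from their gene-cluster vectors.

    Distances use presence (0/1) by default; ``use_counts`` switches to the
    raw gene counts. Leaves are pre-sorted lexicographically so ties break
    identically on every run.
    """
    x = occ.counts.T if use_counts else occ.presence.T
    return _ward(np.asarray(x), occ.genome_ids)


def cluster_gene_clusters(occ: OccurrenceMatrix, use_counts: bool = False) -> Dendrogram:
    """Ward/Euclidean dendrogram of gene clusters from genome distributions."""
    x = occ.counts if use_counts else occ.presence
    return _ward(np.asarray(x), occ.cluster_ids)


def annotation_rate(
    bins: list[BinAssignment],
    clusters: list[GeneCluster],
    annotations: list[AnnotationRecord],
    source: str,
) -> dict[str, float]:
    """Fraction of clusters with >= 1 member annotated by ``source``, per bin.

    Returns one entry per bin present plus an ``OVERALL`` entry. Duplicate
    annotation records do not change the rate.
    """
    sources = {a.source for a in annotations}
    if source not in sources:
        raise MetapanError(
            f"unknown annotation source {source!r}; available: {sorted(sources)}"
        )
    annotated_genes = {a.gene_id for a in annotations if a.source == source}
    bin_of = {b.cluster_id: b.bin for b in bins}
    totals: dict[str, int] = {}
    hits: dict[str, int] = {}
    for c in clusters:
        b = bin_of[c.cluster_id].value
        totals[b] = totals.get(b, 0) + 1
        if any(g in annotated_genes for g in c.member_gene_ids):
            hits[b] = hits.get(b, 0) + 1
    rates = {b: hits.get(b, 0) / totals[b] for b in sorted(totals)}
    rates["OVERALL"] = sum(hits.values()) / sum(totals.values())
    return rates


def write_occurrence_tsv(occ: OccurrenceMatrix, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["cluster_id"] + occ.genome_ids)
        for i, cid in enumerate(occ.cluster_ids):
            w.writerow([cid] + [int(x) for x in occ.counts[i]])


def write_bins_tsv(bins: list[BinAssignment], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["cluster_id", "bin"])
        for b in sorted(bins, key=lambda b: b.cluster_id):
            w.writerow([b.cluster_id, b.bin.value])


def read_bins_tsv(path: str | Path) -> list[BinAssignment]:
    out = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            out.append(BinAssignment(cluster_id=row["cluster_id"],
                                     bin=PangenomeBin(row["bin"])))
    return out
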