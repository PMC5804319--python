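"""Environmental core/accessory classification of genes.

For each genome independently: sum every gene's mean coverage over the
metagenomes in which the genome is detected, take the median of those sums
over all the genome's genes (zeros included), and label a gene an
environmental accessory gene (EAG) when its sum is strictly below
``fraction_of_median_coverage`` (default 0.25) times that median —
otherwise it is an environmental core gene (ECG). A genome detected in no
metagenome gets every gene UNCLASSIFIED. The rule is ratio-based, so
rescaling a genome's coverages leaves every label unchanged.

Also here: per-genome EAG fractions, EAG-enrichment ranking of annotated
functions, and maximal runs of consecutive EAGs along the genome (the
island-like signal).
"""

from __future__ import annotations

import csv
from pathlib import Path

import numpy as np

from .model import (
    AnalysisParams,
    AnnotationRecord,
    EnvClass,
    EnvLabel,
    FunctionConnectivity,
    Genome,
    MetapanError,
)
from .recruitment import DetectionTable

__all__ = [
    "EnvClass",
    "EnvLabel",
    "FunctionConnectivity",
    "classify_genes_env",
    "eag_fraction_per_genome",
    "function_env_connectivity",
    "eag_runs",
    "write_env_labels",
    "read_env_labels",
]


def classify_genes_env(
    gene_cov: dict[str, dict[str, float]],
    detection: DetectionTable,
    genome: Genome,
    params: AnalysisParams | None = None,
) -> list[EnvLabel]:
    """Label every gene of ``genome`` as ECG, EAG or UNCLASSIFIED.

    ``gene_cov`` maps gene_id -> {metagenome_id -> mean coverage}; a cell
    missing for a detected metagenome is fatal.
    """
    params = (params or AnalysisParams()).validate()
    if genome.genome_id not in detection.detected.index:
        raise MetapanError(f"genome {genome.genome_id!r} missing from detection table")
    detected = detection.detected_metagenomes(genome.genome_id)

    if not detected:
        return [
            EnvLabel(
                gene_id=g.gene_id,
                genome_id=genome.genome_id,
                label=EnvClass.UNCLASSIFIED,
                coverage_sum=0.0,
                genome_median_sum=0.0,
            )
            for g in genome.genes
        ]

    sums = {}
    for g in genome.genes:
        if g.gene_id not in gene_cov:
            raise MetapanError(f"no coverage for gene {g.gene_id!r}")
        row = gene_cov[g.gene_id]
        missing = [m for m in detected if m not in row]
        if missing:
            raise MetapanError(
                f"gene {g.gene_id!r}: missing coverage in metagenome(s) {missing[:5]}"
            )
        sums[g.gene_id] = float(sum(row[m] for m in detected))

    median = float(np.median(list(sums.values())))
    cutoff = params.fraction_of_median_coverage * median
    return [
        EnvLabel(
            gene_id=g.gene_id,
            genome_id=genome.genome_id,
            label=EnvClass.EAG if sums[g.gene_id] < cutoff else EnvClass.ECG,
            coverage_sum=sums[g.gene_id],
            genome_median_sum=median,
        )
        for g in genome.genes
    ]


def eag_fraction_per_genome(labels: list[EnvLabel]) -> dict[str, float | None]:
    """EAG / (EAG + ECG) per genome; None when nothing is classified."""
    counts: dict[str, dict[EnvClass, int]] = {}
    for l in labels:
        counts.setdefault(l.genome_id, {}).setdefault(l.label, 0)
        counts[l.genome_id][l.label] += 1
    out: dict[str, float | None] = {}
    for gid, c in sorted(counts.items()):
        classified = c.get(EnvClass.ECG, 0) + c.get(EnvClass.EAG, 0)
        out[gid] = c.get(EnvClass.EAG, 0) / classified if classified else None
    return out


def function_env_connectivity(
    labels: list[EnvLabel],
    annotations: list[AnnotationRecord],
    top_k: int = 25,
) -> list[FunctionConnectivity]:
    """Rank functions by EAG enrichment among classified, annotated genes.

    UNCLASSIFIED genes are excluded entirely. Ranking: eag_ratio desc,
    n_EAG desc, function key asc — deterministic under any input order.
    """
    label_of = {l.gene_id: l.label for l in labels}
    tallies: dict[tuple[str, str, str], list[int]] = {}
    for a in annotations:
        lab = label_of.get(a.gene_id)
        if lab is None or lab is EnvClass.UNCLASSIFIED:
            continue
        key = (a.source, a.accession, a.function_text)
        t = tallies.setdefault(key, [0, 0])
        if lab is EnvClass.ECG:
            t[0] += 1
        else:
            t[1] += 1
    items = [
        FunctionConnectivity(
            source=k[0], accession=k[1], function_text=k[2], n_ecg=t[0], n_eag=t[1]
        )
        for k, t in tallies.items()
        if t[0] + t[1] > 0
    ]
    items.sort(
        key=lambda f: (-f.eag_ratio, -f.n_eag, f.source, f.accession, f.function_text)
    )
    return items[:top_k]


def eag_runs(
    genome: Genome, labels: list[EnvLabel]
) -> list[tuple[str, int, int]]:
    """Maximal runs of consecutive EAG genes in genomic order.

    Returns (contig_id, start_gene_index, run_length) with the gene index
    counted within the genome's position-sorted gene list.
    """
    label_of = {l.gene_id: l.label for l in labels}
    missing = [g.gene_id for g in genome.genes if g.gene_id not in label_of]
    if missing:
        raise MetapanError(f"labels missing for genes {missing[:5]}")
    runs: list[tuple[str, int, int]] = []
    run_start = None
    prev_contig = None
    for i, g in enumerate(genome.genes):
        is_eag = label_of[g.gene_id] is EnvClass.EAG
        new_contig = g.contig_id != prev_contig
        if run_start is not None and (not is_eag or new_contig):
            runs.append((prev_contig, run_start, i - run_start))
            run_start = None
        if is_eag and run_start is None:
            run_start = i
        prev_contig = g.contig_id
    if run_start is not None:
        runs.append((prev_contig, run_start, len(genome.genes) - run_start))
    return runs


def write_env_labels(labels: list[EnvLabel], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["gene_id", "genome_id", "label", "coverage_sum",
                    "genome_median_sum"])
        for l in sorted(labels, key=lambda l: (l.genome_id, l.gene_id)):
            w.writerow([l.gene_id, l.genome_id, l.label.value,
                        f"{l.coverage_sum:.6g}", f"{l.genome_median_sum:.6g}"])


def read_env_labels(path: str | Path) -> list[EnvLabel]:
    out = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            out.append(
                EnvLabel(
                    gene_id=row["gene_id"],
                    genome_id=row["genome_id"],
                    label=EnvClass(row["label"]),
                    coverage_sum=float(row["coverage_sum"]),
                    genome_median_sum=float(row["genome_median_sum"]),
                )
            )
    return out
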