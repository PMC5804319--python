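"""The metapangenome join: pangenome layer x environmental layer.

Each gene cluster is summarized by its bin, genome spread, and the
environmental labels of its member genes; bins are summarized by their
pooled EAG percentage (EAGs over classified genes, UNCLASSIFIED excluded
from every denominator); the whole project exports to one versioned JSON
document ordered by the dendrogram leaf orders.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path

from .model import (
    AnnotationRecord,
    BinAssignment,
    Dendrogram,
    EnvClass,
    EnvLabel,
    GeneCluster,
    MetapanError,
    MetapangenomeSummary,
    PangenomeBin,
)
from .pangenome import OccurrenceMatrix
from .recruitment import DetectionTable

__all__ = [
    "MetapangenomeSummary",
    "SCHEMA_VERSION",
    "summarize_cluster_env",
    "bin_eag_percentage",
    "export_metapangenome",
    "load_metapangenome",
    "validate_export",
    "write_summary_tsv",
]

SCHEMA_VERSION = "metapan-export-1"

_SOURCE_PRIORITY = {"COG": 0, "Pfam": 1, "EggNOG": 2}


def _best_annotation(
    member_ids: list[str], by_gene: dict[str, list[AnnotationRecord]]
) -> tuple[str, str, str] | None:
    """Most frequent function key among members; ties by source priority
    (COG > Pfam > EggNOG > others), then lexicographic key."""
    counts: dict[tuple[str, str, str], int] = {}
    for gid in member_ids:
        for a in by_gene.get(gid, []):
            key = (a.source, a.accession, a.function_text)
            counts[key] = counts.get(key, 0) + 1
    if not counts:
        return None
    return min(
        counts,
        key=lambda k: (-counts[k], _SOURCE_PRIORITY.get(k[0], 99), k),
    )


def summarize_cluster_env(
    clusters: list[GeneCluster],
    labels: list[EnvLabel],
    bins: list[BinAssignment],
    annotations: list[AnnotationRecord] | None = None,
) -> list[MetapangenomeSummary]:
    """Per-cluster ECG/EAG/UNCLASSIFIED composition plus best annotation."""
    label_of = {l.gene_id: l.label for l in labels}
    genome_of = {l.gene_id: l.genome_id for l in labels}
    bin_of = {b.cluster_id: b.bin for b in bins}
    by_gene: dict[str, list[AnnotationRecord]] = {}
    for a in annotations or []:
        by_gene.setdefault(a.gene_id, []).append(a)

    out = []
    for c in sorted(clusters, key=lambda c: c.cluster_id):
        if c.cluster_id not in bin_of:
            raise MetapanError(f"cluster {c.cluster_id} has no bin assignment")
        tally = {EnvClass.ECG: 0, EnvClass.EAG: 0, EnvClass.UNCLASSIFIED: 0}
        for gid in c.member_gene_ids:
            if gid not in label_of:
                raise MetapanError(
                    f"gene {gid!r} in cluster {c.cluster_id} has no env label"
                )
            tally[label_of[gid]] += 1
        out.append(
            MetapangenomeSummary(
                cluster_id=c.cluster_id,
                bin=bin_of[c.cluster_id],
                genomes_present=(
                    len(c.genome_multiplicity)
                    if c.genome_multiplicity
                    else len({genome_of[g] for g in c.member_gene_ids})
                ),
                n_genes=c.size,
                n_ecg=tally[EnvClass.ECG],
                n_eag=tally[EnvClass.EAG],
                n_unclassified=tally[EnvClass.UNCLASSIFIED],
                best_annotation=_best_annotation(c.member_gene_ids, by_gene),
            )
        )
    return out


def bin_eag_percentage(
    summaries: list[MetapangenomeSummary],
) -> dict[str, float | None]:
    """Pooled per-gene EAG percentage per bin: 100 * sum EAG / sum classified.

    A bin with zero classified genes reports None (missing).
    """
    eag: dict[str, int] = {}
    classified: dict[str, int] = {}
    for s in summaries:
        b = s.bin.value
        eag[b] = eag.get(b, 0) + s.n_eag
        classified[b] = classified.get(b, 0) + s.n_ecg + s.n_eag
    return {
        b: (100.0 * eag[b] / classified[b] if classified[b] else None)
        for b in sorted(classified)
    }


def export_metapangenome(
    summaries: list[MetapangenomeSummary],
    occ: OccurrenceMatrix,
    genome_tree: Dendrogram,
    cluster_tree: Dendrogram,
    detection: DetectionTable,
    relative_distributions: dict[str, dict[str, float]],
    path: str | Path,
) -> None:
    """Write the whole project as one JSON document.

    Cluster records follow the gene-cluster dendrogram leaf order and
    genome records the genome dendrogram leaf order, so a reader can redraw
    the layered display without recomputing either clustering.
    """
    by_cluster = {s.cluster_id: s for s in summaries}
    cluster_order = cluster_tree.leaf_order()
    genome_order = genome_tree.leaf_order()
    if set(cluster_order) != set(occ.cluster_ids) or set(cluster_order) != set(
        by_cluster
    ):
        raise MetapanError("cluster ids differ between layers")
    if set(genome_order) != set(occ.genome_ids):
        raise MetapanError("genome ids differ between layers")

    ci = {c: i for i, c in enumerate(occ.cluster_ids)}
    gi = {g: i for i, g in enumerate(occ.genome_ids)}
    doc = {
        "schema_version": SCHEMA_VERSION,
        "clusters": [
            {
                "cluster_id": cid,
                "bin": by_cluster[cid].bin.value,
                "genomes_present": by_cluster[cid].genomes_present,
                "n_genes": by_cluster[cid].n_genes,
                "n_ecg": by_cluster[cid].n_ecg,
                "n_eag": by_cluster[cid].n_eag,
                "n_unclassified": by_cluster[cid].n_unclassified,
                "eag_ratio": by_cluster[cid].eag_ratio,
                "best_annotation": (
                    list(by_cluster[cid].best_annotation)
                    if by_cluster[cid].best_annotation
                    else None
                ),
                "occurrence": {
                    g: int(occ.counts[ci[cid], gi[g]])
                    for g in occ.genome_ids
                    if occ.counts[ci[cid], gi[g]]
                },
            }
            for cid in cluster_order
        ],
        "genomes": [
            {
                "genome_id": g,
                "detection": {
                    m: bool(detection.detected.loc[g, m])
                    for m in detection.detected.columns
                },
                "breadth": {
                    m: float(detection.breadth.loc[g, m])
                    for m in detection.breadth.columns
                },
                "relative_distribution": {
                    m: float(v)
                    for m, v in sorted(
                        relative_distributions.get(g, {}).items()
                    )
                },
            }
            for g in genome_order
        ],
        "genome_tree": {"labels": genome_order},
        "cluster_tree": {"labels": cluster_order},
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1, sort_keys=False)
        fh.write("\n")


def load_metapangenome(path: str | Path) -> dict:
    with open(path) as fh:
        doc = json.load(fh)
    validate_export(doc)
    return doc


def validate_export(doc: dict) -> None:
    """Check a loaded export against the shipped schema."""
    schema_path = Path(__file__).parent / "export_schema.json"
    with open(schema_path) as fh:
        schema = json.load(fh)
    if doc.get("schema_version") != schema["schema_version"]:
        raise MetapanError(
            f"schema version {doc.get('schema_version')!r} != "
            f"{schema['schema_version']!r}"
        )
    for key in schema["required"]:
        if key not in doc:
            raise MetapanError(f"export missing key {key!r}")
    for rec in doc["clusters"]:
        missing = set(schema["cluster_record_required"]) - set(rec)
        if missing:
            raise MetapanError(f"cluster record missing {sorted(missing)}")
        if rec["n_ecg"] + rec["n_eag"] + rec["n_unclassified"] != rec["n_genes"]:
            raise MetapanError(
                f"cluster {rec['cluster_id']}: label counts do not sum to n_genes"
            )
    for rec in doc["genomes"]:
        missing = set(schema["genome_record_required"]) - set(rec)
        if missing:
            raise MetapanError(f"genome record missing {sorted(missing)}")
    if [r["cluster_id"] for r in doc["clusters"]] != doc["cluster_tree"]["labels"]:
        raise MetapanError("cluster order does not match dendrogram leaf order")
    if [r["genome_id"] for r in doc["genomes"]] != doc["genome_tree"]["labels"]:
        raise MetapanError("genome order does not match dendrogram leaf order")


def write_summary_tsv(
    summaries: list[MetapangenomeSummary], path: str | Path
) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(
            ["cluster_id", "bin", "genomes_present", "n_genes", "n_ecg",
             "n_eag", "n_unclassified", "eag_ratio", "annotation_source",
             "annotation_accession", "annotation_function"]
        )
        for s in sorted(summaries, key=lambda s: s.cluster_id):
            ann = s.best_annotation or ("", "", "")
            ratio = "" if s.eag_ratio is None else f"{s.eag_ratio:.6g}"
            w.writerow(
                [s.cluster_id, s.bin.value, s.genomes_present, s.n_genes,
                 s.n_ecg, s.n_eag, s.n_unclassified, ratio, *ann]
            )
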