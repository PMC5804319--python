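"""Readers and writers for all external formats.

Inputs: genome FASTA, tabular gene calls, companion amino-acid FASTA,
clade -> light-class maps, BLAST outfmt-6-style hits tables and annotation
tables. Outputs: TSV summaries and newick dendrograms. Every writer has a
matching reader and write-then-read is the identity on the data model.
"""

from __future__ import annotations

import csv
import logging
from pathlib import Path

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq

from .model import (
    AnalysisParams,
    AnnotationRecord,
    Dendrogram,
    GeneCall,
    Genome,
    HitRecord,
    MetapanError,
)

__all__ = [
    "AnalysisParams",
    "AnnotationRecord",
    "GeneCall",
    "Genome",
    "read_fasta",
    "write_fasta",
    "read_gene_calls",
    "write_gene_calls",
    "read_genome_bundle",
    "read_clade_map",
    "read_genomes_table",
    "read_hits_table",
    "write_hits_table",
    "read_annotations",
    "write_annotations",
    "sanitize_label",
    "write_newick",
    "dendrogram_to_newick",
]

logger = logging.getLogger(__name__)

GENE_CALL_COLUMNS = ["gene_id", "genome_id", "contig", "start", "stop", "strand", "partial"]
OUTFMT6_COLUMNS = [
    "query", "subject", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an id -> uppercase sequence mapping."""
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seqs:
            raise MetapanError(f"{path}: duplicate FASTA id {rec.id!r}")
        seqs[rec.id] = str(rec.seq).upper()
    return seqs


def write_fasta(seqs: dict[str, str], path: str | Path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name in seqs:
            fh.write(f">{name}\n")
            s = seqs[name]
            for i in range(0, len(s), width):
                fh.write(s[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Gene calls

def write_gene_calls(genes: list[GeneCall], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(GENE_CALL_COLUMNS)
        for g in genes:
            w.writerow(
                [g.gene_id, g.genome_id, g.contig_id, g.start, g.stop,
                 g.strand, int(g.partial)]
            )


def read_gene_calls(path: str | Path) -> list[dict]:
    """Read a gene-calls TSV into plain row dicts (sequences attached later)."""
    rows: list[dict] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        missing = set(GENE_CALL_COLUMNS) - set(reader.fieldnames or [])
        if missing:
            raise MetapanError(f"{path}: missing gene-call columns {sorted(missing)}")
        for row in reader:
            rows.append(
                {
                    "gene_id": row["gene_id"],
                    "genome_id": row["genome_id"],
                    "contig": row["contig"],
                    "start": int(row["start"]),
                    "stop": int(row["stop"]),
                    "strand": row["strand"],
                    "partial": row["partial"] in ("1", "True", "true"),
                }
            )
    return rows


_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def _translate_span(contig_seq: str, start: int, stop: int, strand: str,
                    gene_id: str) -> str:
    nt = contig_seq[start:stop]
    bad = set(nt) - set("ACGTN")
    if bad:
        logger.warning(
            "gene %s: non-ACGTN nucleotides %s, translating with X",
            gene_id, sorted(bad),
        )
        nt = "".join(c if c in "ACGTN" else "N" for c in nt)
    if strand == "-":
        nt = nt.translate(_COMPLEMENT)[::-1]
    aa = str(Seq(nt[: len(nt) - len(nt) % 3]).translate())
    return aa[:-1] if aa.endswith("*") else aa


def read_genome_bundle(
    fasta_path: str | Path,
    gene_calls_path: str | Path,
    aa_fasta_path: str | Path | None = None,
    genome_id: str | None = None,
    clade_label: str = "",
    light_class: str = "other",
) -> Genome:
    """Assemble a validated :class:`Genome` from its on-disk bundle.

    Amino-acid sequences come from the companion FASTA when given, otherwise
    they are translated from the nucleotide span (standard code, stop codon
    dropped, reverse strand reverse-complemented first).
    """
    contigs = read_fasta(fasta_path)
    rows = read_gene_calls(gene_calls_path)
    if genome_id is not None:
        rows = [r for r in rows if r["genome_id"] == genome_id]
        if not rows:
            raise MetapanError(f"{gene_calls_path}: no gene calls for {genome_id!r}")
    else:
        ids = {r["genome_id"] for r in rows}
        if len(ids) != 1:
            raise MetapanError(
                f"{gene_calls_path}: expected a single genome, found {sorted(ids)}"
            )
        genome_id = ids.pop()

    aa_seqs = read_fasta(aa_fasta_path) if aa_fasta_path else {}
    genes = []
    for r in rows:
        if r["contig"] not in contigs:
            raise MetapanError(
                f"gene {r['gene_id']!r}: contig {r['contig']!r} not in {fasta_path}"
            )
        contig_seq = contigs[r["contig"]]
        if r["stop"] > len(contig_seq):
            raise MetapanError(
                f"gene {r['gene_id']!r}: span [{r['start']}, {r['stop']}) exceeds "
                f"contig length {len(contig_seq)}"
            )
        aa = aa_seqs.get(r["gene_id"]) or _translate_span(
            contig_seq, r["start"], r["stop"], r["strand"], r["gene_id"]
        )
        genes.append(
            GeneCall(
                gene_id=r["gene_id"],
                genome_id=genome_id,
                contig_id=r["contig"],
                start=r["start"],
                stop=r["stop"],
                strand=r["strand"],
                partial=r["partial"],
                aa_seq=aa,
            )
        )
    return Genome(
        genome_id=genome_id,
        clade_label=clade_label,
        light_class=light_class,
        contigs=sorted((cid, len(s)) for cid, s in contigs.items()),
        genes=genes,
    )


def read_clade_map(path: str | Path) -> dict[str, str]:
    """Two-column TSV mapping clade label -> light class (HL/LL/other)."""
    mapping: dict[str, str] = {}
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader, None)
        if header is None:
            raise MetapanError(f"{path}: empty clade map")
        # accept files with or without a header row
        if header[0].lower() not in ("clade", "clade_label"):
            mapping[header[0]] = header[1]
        for row in reader:
            if row:
                mapping[row[0]] = row[1]
    for clade, cls in mapping.items():
        if cls not in ("HL", "LL", "other"):
            raise MetapanError(
                f"clade {clade!r}: light class must be HL, LL or other, got {cls!r}"
            )
    return mapping


def read_genomes_table(path: str | Path, clade_map: dict[str, str]) -> list[Genome]:
    """Read a project's genomes-list TSV.

    Columns: genome_id, clade, fasta, gene_calls and optional aa_fasta; paths
    are resolved relative to the table's directory.
    """
    base = Path(path).parent
    genomes = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        required = {"genome_id", "clade", "fasta", "gene_calls"}
        missing = required - set(reader.fieldnames or [])
        if missing:
            raise MetapanError(f"{path}: missing columns {sorted(missing)}")
        for row in reader:
            clade = row["clade"]
            if clade not in clade_map:
                raise MetapanError(f"genome {row['genome_id']!r}: unknown clade {clade!r}")
            aa = row.get("aa_fasta") or None
            genomes.append(
                read_genome_bundle(
                    base / row["fasta"],
                    base / row["gene_calls"],
                    base / aa if aa else None,
                    genome_id=row["genome_id"],
                    clade_label=clade,
                    light_class=clade_map[clade],
                )
            )
    return sorted(genomes, key=lambda g: g.genome_id)


# ---------------------------------------------------------------------------
# Hits (BLAST outfmt 6)

def read_hits_table(path: str | Path, known_gene_ids: set[str] | None = None
                    ) -> list[HitRecord]:
    """Read an outfmt-6-style hits TSV (12+ columns, extras ignored).

    Self-hits are retained: they carry the self-scores the minbit
    normalisation needs.
    """
    hits: list[HitRecord] = []
    warned_extra = False
    with open(path, newline="") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 12:
                raise MetapanError(
                    f"{path}:{lineno}: expected >=12 tab-separated columns "
                    f"(outfmt 6), got {len(parts)} — bitscore column missing"
                )
            if len(parts) > 12 and not warned_extra:
                logger.warning("%s: more than 12 columns; extras ignored", path)
                warned_extra = True
            hits.append(
                HitRecord(
                    query_id=parts[0],
                    subject_id=parts[1],
                    percent_identity=float(parts[2]),
                    align_length=int(parts[3]),
                    bitscore=float(parts[11]),
                )
            )
    if not hits:
        logger.warning("%s: empty hits table", path)
    if known_gene_ids is not None:
        unknown = sorted(
            ({h.query_id for h in hits} | {h.subject_id for h in hits})
            - known_gene_ids
        )
        if unknown:
            raise MetapanError(
                f"{path}: {len(unknown)} unknown gene ids, first 10: {unknown[:10]}"
            )
    return hits


def write_hits_table(hits: list[HitRecord], path: str | Path) -> None:
    """Write hits in outfmt-6 column order (unused columns zero-filled)."""
    with open(path, "w", newline="") as fh:
        for h in hits:
            fh.write(
                "\t".join(
                    [
                        h.query_id, h.subject_id, f"{h.percent_identity:.2f}",
                        str(h.align_length), "0", "0", "0", "0", "0", "0",
                        "0.0", f"{h.bitscore:.1f}",
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# Annotations

def read_annotations(path: str | Path) -> list[AnnotationRecord]:
    records = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        required = {"gene_id", "source", "accession", "function"}
        missing = required - set(reader.fieldnames or [])
        if missing:
            raise MetapanError(f"{path}: missing annotation columns {sorted(missing)}")
        for row in reader:
            records.append(
                AnnotationRecord(
                    gene_id=row["gene_id"],
                    source=row["source"],
                    accession=row["accession"],
                    function_text=row["function"],
                )
            )
    return records


def write_annotations(records: list[AnnotationRecord], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["gene_id", "source", "accession", "function"])
        for r in records:
            w.writerow([r.gene_id, r.source, r.accession, r.function_text])


# ---------------------------------------------------------------------------
# Newick

def sanitize_label(label: str) -> str:
    """Replace newick-reserved characters and whitespace with underscores."""
    out = []
    for c in label:
        out.append("_" if c in ";:(),'[]" or c.isspace() else c)
    return "".join(out)


def dendrogram_to_newick(tree: Dendrogram) -> str:
    """Serialize a dendrogram to newick with branch lengths.

    Branch length of a node is its parent's merge height minus its own
    height (leaves sit at height 0).
    """
    labels = [sanitize_label(l) for l in tree.labels]
    if len(set(labels)) != len(labels):
        raise MetapanError("duplicate leaf labels after sanitization")

    from scipy.cluster.hierarchy import to_tree

    root = to_tree(tree.linkage)

    def recurse(node, parent_height: float) -> str:
        bl = parent_height - node.dist
        if node.is_leaf():
            return f"{labels[node.id]}:{bl:.10g}"
        left = recurse(node.left, node.dist)
        right = recurse(node.right, node.dist)
        return f"({left},{right}):{bl:.10g}"

    left = recurse(root.left, root.dist)
    right = recurse(root.right, root.dist)
    return f"({left},{right});"


def write_newick(tree: Dendrogram, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(dendrogram_to_newick(tree) + "\n")
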