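"""Metagenomic read-recruitment profiles: coverage, breadth, detection.

The canonical interchange is a pair of tables per project — per-gene mean
coverage (genes x metagenomes) and per-genome breadth (genomes x
metagenomes) — plus per-metagenome read totals. A sorted/indexed BAM can
stand in for the tables through :func:`profile_bam`, which computes the
same quantities from per-position depths (each aligned read base counts
once; mapping quality is ignored).

A genome is *detected* in a metagenome when strictly more than half of its
nucleotide positions have at least 1X coverage — breadth exactly 0.5 is
not detection. Detection gates the downstream environmental-core/accessory
classification.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .model import AnalysisParams, GeneCall, Genome, MetapanError

__all__ = [
    "CoverageProfile",
    "DetectionTable",
    "gene_mean_coverage",
    "genome_breadth",
    "build_detection_table",
    "relative_distribution",
    "profile_bam",
    "profile_depth_vectors",
    "read_coverage_tables",
    "write_coverage_tables",
]

logger = logging.getLogger(__name__)


@dataclass
class CoverageProfile:
    """Recruitment summary of one metagenome against the project's genomes."""

    metagenome_id: str
    mean_coverage: dict[str, float]          # gene_id -> mean depth
    breadth: dict[str, float]                # genome_id -> covered fraction
    mapped_read_counts: dict[str, int] = field(default_factory=dict)
    total_reads: int = 0

    def __post_init__(self) -> None:
        for gid, b in self.breadth.items():
            if not 0.0 <= b <= 1.0:
                raise MetapanError(
                    f"{self.metagenome_id}/{gid}: breadth {b} outside [0, 1]"
                )
        if any(v < 0 for v in self.mean_coverage.values()):
            raise MetapanError(f"{self.metagenome_id}: negative mean coverage")
        if self.total_reads and sum(self.mapped_read_counts.values()) > self.total_reads:
            raise MetapanError(
                f"{self.metagenome_id}: mapped reads exceed total reads"
            )


@dataclass
class DetectionTable:
    """Genome x metagenome breadth values and the derived detection flags."""

    breadth: pd.DataFrame    # genomes x metagenomes, float
    detected: pd.DataFrame   # same shape, bool

    def detected_metagenomes(self, genome_id: str) -> list[str]:
        row = self.detected.loc[genome_id]
        return [m for m in self.detected.columns if bool(row[m])]


def gene_mean_coverage(depth_vector: np.ndarray, gene: GeneCall) -> float:
    """Arithmetic mean depth over the gene's span ``[start, stop)``."""
    if gene.stop > len(depth_vector):
        raise MetapanError(
            f"gene {gene.gene_id!r}: span exceeds depth vector "
            f"({gene.stop} > {len(depth_vector)})"
        )
    return float(np.mean(depth_vector[gene.start : gene.stop]))


def genome_breadth(
    depth_vectors: dict[str, np.ndarray], genome: Genome, min_depth: float = 1.0
) -> float:
    """Fraction of the genome's positions at depth >= ``min_depth``.

    Pooled across contigs, so the value is invariant to contig order and
    to splitting any contig's vector.
    """
    covered = 0
    total = 0
    for contig_id, length in genome.contigs:
        if contig_id not in depth_vectors:
            raise MetapanError(f"no depth vector for contig {contig_id!r}")
        vec = depth_vectors[contig_id]
        if len(vec) != length:
            raise MetapanError(
                f"contig {contig_id!r}: depth vector length {len(vec)} != {length}"
            )
        covered += int(np.count_nonzero(vec >= min_depth))
        total += length
    if total == 0:
        raise MetapanError(f"genome {genome.genome_id!r} has zero length")
    return covered / total


def build_detection_table(
    profiles: list[CoverageProfile], params: AnalysisParams | None = None
) -> DetectionTable:
    """Detection flags from breadth: detected iff breadth > threshold (strict)."""
    params = (params or AnalysisParams()).validate()
    genome_ids = sorted({g for p in profiles for g in p.breadth})
    metagenome_ids = sorted(p.metagenome_id for p in profiles)
    if len(set(metagenome_ids)) != len(metagenome_ids):
        raise MetapanError("duplicate metagenome ids")
    by_id = {p.metagenome_id: p for p in profiles}
    data = np.zeros((len(genome_ids), len(metagenome_ids)))
    for j, mid in enumerate(metagenome_ids):
        for i, gid in enumerate(genome_ids):
            if gid not in by_id[mid].breadth:
                raise MetapanError(f"missing breadth for {gid!r} in {mid!r}")
            data[i, j] = by_id[mid].breadth[gid]
    breadth = pd.DataFrame(data, index=genome_ids, columns=metagenome_ids)
    detected = breadth > params.detection_breadth_threshold
    return DetectionTable(breadth=breadth, detected=detected)


def relative_distribution(profile: CoverageProfile, genome_id: str) -> float:
    """Percent of the metagenome's quality-filtered reads recruited by a genome."""
    if profile.total_reads <= 0:
        raise MetapanError(
            f"{profile.metagenome_id}: total_reads must be positive"
        )
    return 100.0 * profile.mapped_read_counts.get(genome_id, 0) / profile.total_reads


# ---------------------------------------------------------------------------
# Depth-vector and BAM backends

def profile_depth_vectors(
    depth_vectors: dict[str, np.ndarray],
    genomes: list[Genome],
    metagenome_id: str,
    mapped_read_counts: dict[str, int] | None = None,
    total_reads: int = 0,
    min_depth: float = 1.0,
) -> CoverageProfile:
    """Build a profile from explicit per-contig per-position depth vectors."""
    mean_cov = {}
    breadth = {}
    for genome in genomes:
        for gene in genome.genes:
            mean_cov[gene.gene_id] = gene_mean_coverage(
                depth_vectors[gene.contig_id], gene
            )
        breadth[genome.genome_id] = genome_breadth(depth_vectors, genome, min_depth)
    return CoverageProfile(
        metagenome_id=metagenome_id,
        mean_coverage=mean_cov,
        breadth=breadth,
        mapped_read_counts=mapped_read_counts or {},
        total_reads=total_reads,
    )


def profile_bam(
    bam_path: str | Path,
    genomes: list[Genome],
    metagenome_id: str | None = None,
    total_reads: int = 0,
    min_depth: float = 1.0,
) -> CoverageProfile:
    """Profile a sorted, indexed BAM whose references are the project contigs.

    Depth counts each aligned read base once (secondary/supplementary
    alignments excluded); mapped read counts per genome come from the
    index statistics. Unknown references are skipped with a warning.
    """
    import pysam

    bam_path = Path(bam_path)
    metagenome_id = metagenome_id or bam_path.stem
    contig_lengths = {cid: ln for g in genomes for cid, ln in g.contigs}
    contig_genome = {cid: g.genome_id for g in genomes for cid, _ in g.contigs}

    with pysam.AlignmentFile(str(bam_path), "rb") as bam:
        if not bam.has_index():
            raise MetapanError(f"{bam_path}: BAM index required (samtools index)")
        depth_vectors: dict[str, np.ndarray] = {
            cid: np.zeros(ln) for cid, ln in contig_lengths.items()
        }
        for ref in bam.references:
            if ref not in contig_lengths:
                logger.warning("%s: unknown reference %r skipped", bam_path, ref)
                continue
            acgt = bam.count_coverage(
                ref, 0, contig_lengths[ref], quality_threshold=0
            )
            depth_vectors[ref] = np.sum(np.array(acgt, dtype=float), axis=0)
        mapped: dict[str, int] = {g.genome_id: 0 for g in genomes}
        for stat in bam.get_index_statistics():
            if stat.contig in contig_genome:
                mapped[contig_genome[stat.contig]] += stat.mapped
    return profile_depth_vectors(
        depth_vectors, genomes, metagenome_id, mapped, total_reads, min_depth
    )


# ---------------------------------------------------------------------------
# TSV interchange

def write_coverage_tables(profiles: list[CoverageProfile], out_dir: str | Path) -> None:
    """Write gene_coverage.tsv, breadth.tsv, mapped_reads.tsv, metagenome_meta.tsv."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    mids = sorted(p.metagenome_id for p in profiles)
    by_id = {p.metagenome_id: p for p in profiles}

    gene_ids = sorted({g for p in profiles for g in p.mean_coverage})
    genome_ids = sorted({g for p in profiles for g in p.breadth})

    def frame(attr: str, index: list[str]) -> pd.DataFrame:
        data = {
            mid: [getattr(by_id[mid], attr).get(i, 0.0) for i in index]
            for mid in mids
        }
        return pd.DataFrame(data, index=index)

    frame("mean_coverage", gene_ids).rename_axis("gene_id").to_csv(
        out_dir / "gene_coverage.tsv", sep="\t", float_format="%.10g"
    )
    frame("breadth", genome_ids).rename_axis("genome_id").to_csv(
        out_dir / "breadth.tsv", sep="\t", float_format="%.10g"
    )
    frame("mapped_read_counts", genome_ids).rename_axis("genome_id").astype(int).to_csv(
        out_dir / "mapped_reads.tsv", sep="\t"
    )
    with open(out_dir / "metagenome_meta.tsv", "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["metagenome_id", "total_reads"])
        for mid in mids:
            w.writerow([mid, by_id[mid].total_reads])


def read_coverage_tables(in_dir: str | Path) -> list[CoverageProfile]:
    """Read the coverage-table bundle back into per-metagenome profiles."""
    in_dir = Path(in_dir)
    cov = pd.read_csv(in_dir / "gene_coverage.tsv", sep="\t", index_col=0)
    breadth = pd.read_csv(in_dir / "breadth.tsv", sep="\t", index_col=0)
    if list(cov.columns) != list(breadth.columns):
        raise MetapanError("gene_coverage and breadth metagenome columns differ")
    mapped_path = in_dir / "mapped_reads.tsv"
    mapped = (
        pd.read_csv(mapped_path, sep="\t", index_col=0)
        if mapped_path.exists()
        else None
    )
    totals: dict[str, int] = {}
    meta_path = in_dir / "metagenome_meta.tsv"
    if meta_path.exists():
        meta = pd.read_csv(meta_path, sep="\t")
        totals = dict(zip(meta["metagenome_id"], meta["total_reads"].astype(int)))
    profiles = []
    for mid in cov.columns:
        profiles.append(
            CoverageProfile(
                metagenome_id=mid,
                mean_coverage=dict(zip(cov.index, cov[mid].astype(float))),
                breadth=dict(zip(breadth.index, breadth[mid].astype(float))),
                mapped_read_counts=(
                    dict(zip(mapped.index, mapped[mid].astype(int)))
                    if mapped is not None
                    else {}
                ),
                total_reads=int(totals.get(mid, 0)),
            )
        )
    return profiles
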