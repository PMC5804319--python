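"""Shared data model for the metapangenome pipeline.

Every analysis stage exchanges the small set of dataclasses defined here:
gene calls and genomes on the way in, homology hits and minbit edges in the
clustering layer, gene clusters and occurrence matrices in the pangenome
layer, and coverage/detection objects in the metagenomic layer.

Coordinates are 0-based, half-open ``[start, stop)`` on the forward strand;
strand only affects translation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np


class MetapanError(ValueError):
    """Raised for invalid inputs anywhere in the pipeline."""


@dataclass(frozen=True)
class GeneCall:
    """One called gene: location on a contig plus its amino-acid sequence.

    ``aa_seq`` excludes the stop codon. Partial genes are accepted with any
    amino-acid length; complete genes must span a multiple of 3 nucleotides.
    """

    gene_id: str
    genome_id: str
    contig_id: str
    start: int
    stop: int
    strand: str
    partial: bool = False
    aa_seq: str = ""

    def __post_init__(self) -> None:
        if self.start < 0 or self.stop <= self.start:
            raise MetapanError(
                f"gene {self.gene_id!r}: invalid span [{self.start}, {self.stop})"
            )
        if self.strand not in ("+", "-"):
            raise MetapanError(f"gene {self.gene_id!r}: strand must be '+' or '-'")
        if not self.partial and (self.stop - self.start) % 3 != 0:
            raise MetapanError(
                f"gene {self.gene_id!r}: complete gene length not a multiple of 3"
            )

    @property
    def length(self) -> int:
        return self.stop - self.start


@dataclass
class Genome:
    """A genome: contigs plus its gene calls ordered by genomic position."""

    genome_id: str
    clade_label: str = ""
    light_class: str = "other"
    contigs: list[tuple[str, int]] = field(default_factory=list)
    genes: list[GeneCall] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.genes = sorted(self.genes, key=lambda g: (g.contig_id, g.start))
        lengths = dict(self.contigs)
        for g in self.genes:
            if g.contig_id not in lengths:
                raise MetapanError(
                    f"gene {g.gene_id!r} references unknown contig {g.contig_id!r}"
                )
            if g.stop > lengths[g.contig_id]:
                raise MetapanError(
                    f"gene {g.gene_id!r} extends past the end of contig "
                    f"{g.contig_id!r} ({g.stop} > {lengths[g.contig_id]})"
                )

    @property
    def total_length(self) -> int:
        return sum(length for _, length in self.contigs)

    @property
    def n_genes(self) -> int:
        return len(self.genes)


@dataclass(frozen=True)
class AnnotationRecord:
    """One functional annotation of a gene from a named source (COG, Pfam, ...)."""

    gene_id: str
    source: str
    accession: str
    function_text: str


@dataclass
class AnalysisParams:
    """Tunable parameters of the whole workflow.

    Defaults are the workflow's canonical values: minbit threshold 0.5, MCL
    inflation 10, genome detection at breadth > 0.5 with >= 1X depth, and the
    environmental-accessory rule at 25% of the genome's median gene coverage.
    """

    minbit_threshold: float = 0.5
    mcl_inflation: float = 10.0
    detection_breadth_threshold: float = 0.5
    min_depth_for_detection: float = 1.0
    fraction_of_median_coverage: float = 0.25
    mcl_prune_epsilon: float = 1e-8
    mcl_max_iterations: int = 100
    mcl_convergence_tol: float = 1e-6
    rng_seed: int = 0

    def validate(self) -> "AnalysisParams":
        for name in (
            "minbit_threshold",
            "detection_breadth_threshold",
            "fraction_of_median_coverage",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise MetapanError(f"{name} must be in [0, 1], got {v}")
        if self.mcl_inflation <= 1.0:
            raise MetapanError(f"mcl_inflation must be > 1, got {self.mcl_inflation}")
        if self.min_depth_for_detection < 0:
            raise MetapanError("min_depth_for_detection must be >= 0")
        if self.mcl_prune_epsilon < 0:
            raise MetapanError("mcl_prune_epsilon must be >= 0")
        if self.mcl_max_iterations < 1:
            raise MetapanError("mcl_max_iterations must be >= 1")
        return self


@dataclass(frozen=True)
class HitRecord:
    """A pairwise amino-acid similarity hit (BLAST outfmt-6 semantics)."""

    query_id: str
    subject_id: str
    percent_identity: float
    align_length: int
    bitscore: float

    def __post_init__(self) -> None:
        if self.bitscore < 0:
            raise MetapanError(
                f"hit {self.query_id}->{self.subject_id}: negative bitscore"
            )
        if self.align_length < 1:
            raise MetapanError(
                f"hit {self.query_id}->{self.subject_id}: align_length < 1"
            )


@dataclass(frozen=True)
class MinbitEdge:
    """An undirected, minbit-weighted edge of the homology graph.

    Canonical ordering ``gene_a < gene_b``; self-edges are never stored
    (MCL adds its own self-loops).
    """

    gene_a: str
    gene_b: str
    minbit: float
    weight: float

    def __post_init__(self) -> None:
        if self.gene_a >= self.gene_b:
            raise MetapanError(
                f"edge ({self.gene_a}, {self.gene_b}) not in canonical order"
            )
        if self.minbit < 0 or self.weight < 0:
            raise MetapanError("minbit and weight must be non-negative")


@dataclass
class GeneCluster:
    """A homology cluster: one or more genes grouped across genomes."""

    cluster_id: str
    member_gene_ids: list[str]
    genome_multiplicity: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.member_gene_ids)) != len(self.member_gene_ids):
            raise MetapanError(f"cluster {self.cluster_id}: duplicate members")
        if not self.member_gene_ids:
            raise MetapanError(f"cluster {self.cluster_id}: empty")

    @property
    def size(self) -> int:
        return len(self.member_gene_ids)


class PangenomeBin(str, Enum):
    """The five occurrence-based pangenome bins."""

    CORE_ALL = "CORE_ALL"
    CORE_HL = "CORE_HL"
    CORE_LL = "CORE_LL"
    SINGLETON = "SINGLETON"
    OTHER = "OTHER"


@dataclass(frozen=True)
class BinAssignment:
    cluster_id: str
    bin: PangenomeBin


@dataclass
class Dendrogram:
    """An agglomerative clustering result: scipy-style linkage plus labels."""

    linkage: np.ndarray
    labels: list[str]
    method: str = "ward"
    metric: str = "euclidean"

    def __post_init__(self) -> None:
        n = len(self.labels)
        if n < 2:
            raise MetapanError("a dendrogram needs at least 2 leaves")
        if self.linkage.shape != (n - 1, 4):
            raise MetapanError(
                f"linkage shape {self.linkage.shape} does not match {n} leaves"
            )
        heights = self.linkage[:, 2]
        if np.any(heights < -1e-12):
            raise MetapanError("negative merge height")

    @property
    def n_leaves(self) -> int:
        return len(self.labels)

    def leaf_order(self) -> list[str]:
        """Labels in dendrogram display order (left to right)."""
        from scipy.cluster.hierarchy import leaves_list

        return [self.labels[i] for i in leaves_list(self.linkage)]


class EnvClass(str, Enum):
    """Environmental connectivity of a gene across its genome's niche."""

    ECG = "ECG"
    EAG = "EAG"
    UNCLASSIFIED = "UNCLASSIFIED"


@dataclass(frozen=True)
class EnvLabel:
    """Environmental label of one gene plus the numbers that produced it."""

    gene_id: str
    genome_id: str
    label: EnvClass
    coverage_sum: float
    genome_median_sum: float


@dataclass(frozen=True)
class FunctionConnectivity:
    """EAG enrichment of one function across all classified genes."""

    source: str
    accession: str
    function_text: str
    n_ecg: int
    n_eag: int

    @property
    def eag_ratio(self) -> float:
        return self.n_eag / (self.n_ecg + self.n_eag)


@dataclass
class MetapangenomeSummary:
    """Per-cluster join of the pangenome and environmental layers."""

    cluster_id: str
    bin: PangenomeBin
    genomes_present: int
    n_genes: int
    n_ecg: int
    n_eag: int
    n_unclassified: int
    best_annotation: tuple[str, str, str] | None = None

    def __post_init__(self) -> None:
        if self.n_ecg + self.n_eag + self.n_unclassified != self.n_genes:
            raise MetapanError(
                f"cluster {self.cluster_id}: ECG+EAG+UNCLASSIFIED != n_genes"
            )

    @property
    def eag_ratio(self) -> float | None:
        classified = self.n_ecg + self.n_eag
        if classified == 0:
            return None
        return self.n_eag / classified
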