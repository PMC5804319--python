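"""Synthetic metapangenome projects with known ground truth.

The generator plants the structure the analysis is meant to recover:

* gene families shared by every genome (universal core), families restricted
  to one light class (clade core), families private to one genome
  (singletons), and patchy accessory families;
* sequence divergence *within* families far above the identity between
  independent families, so homology clustering has a well-defined answer;
* per-metagenome genome abundances (a clade x metagenome coverage plan)
  that decide detection;
* contiguous island blocks of genes whose coverage is suppressed by a
  multiplier (~0), emulating hypervariable islands that recruit no reads.

Everything is driven by one integer seed; the same seed yields
byte-identical files. Evaluation helpers compare predicted clusters, bins
and environmental labels against the planted truth.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .model import (
    AnnotationRecord,
    EnvClass,
    GeneCall,
    GeneCluster,
    Genome,
    MetapanError,
    PangenomeBin,
)
from .recruitment import CoverageProfile
from . import io_formats, recruitment

__all__ = [
    "SimulationParams",
    "TruthTable",
    "SyntheticProject",
    "ReadFixture",
    "simulate_pangenome",
    "simulate_coverage",
    "simulate_read_fixture",
    "evaluate_against_truth",
    "write_project",
]

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"

# one codon per residue for deterministic back-translation
_CODON = {
    "A": "GCT", "C": "TGT", "D": "GAT", "E": "GAA", "F": "TTT",
    "G": "GGT", "H": "CAT", "I": "ATT", "K": "AAA", "L": "CTG",
    "M": "ATG", "N": "AAT", "P": "CCG", "Q": "CAA", "R": "CGT",
    "S": "TCT", "T": "ACT", "V": "GTT", "W": "TGG", "Y": "TAT",
}
_STOP = "TAA"


@dataclass
class SimulationParams:
    """Knobs of the synthetic study; defaults are the generator's canonical
    conditions (8 genomes in 2 light-class clades, 50 universal core + 10
    clade-core families per class, 5 singletons per genome, one island of 8
    genes per genome with coverage multiplier 0)."""

    clade_plan: list[tuple[str, str, int]] = field(
        default_factory=lambda: [("HLS1", "HL", 4), ("LLS1", "LL", 4)]
    )
    n_core_families: int = 50
    n_clade_core_families: int = 10       # per light class
    n_singletons_per_genome: int = 5
    n_other_families: int = 16
    other_presence_prob: float = 0.5
    islands_per_genome: int = 1
    island_len: int = 8                   # genes per island block
    within_identity: float = 0.9
    between_identity_ceiling: float = 0.2
    aa_len_range: tuple[int, int] = (60, 120)
    intergenic_len: int = 30
    n_metagenomes: int = 8
    abundance_plan: dict[tuple[str, str], float] | None = None
    island_multiplier: float = 0.0
    coverage_dispersion: float = 0.1      # sd as a fraction of the mean
    detected_breadth: float = 0.95
    undetected_breadth: float = 0.02
    read_len: int = 100
    total_reads_per_metagenome: int = 10_000_000
    annotation_prob: float = 0.9
    rng_seed: int = 42

    def validate(self) -> "SimulationParams":
        if not 0 < self.within_identity <= 1:
            raise MetapanError("within_identity must be in (0, 1]")
        if self.within_identity <= self.between_identity_ceiling:
            raise MetapanError("within-family identity must exceed the "
                               "between-family ceiling")
        if self.island_len < 1 or self.islands_per_genome < 0:
            raise MetapanError("invalid island layout")
        if not self.clade_plan:
            raise MetapanError("clade plan is empty")
        return self

    @property
    def metagenome_ids(self) -> list[str]:
        return [f"MG_{i + 1:02d}" for i in range(self.n_metagenomes)]

    def default_abundance_plan(self) -> dict[tuple[str, str], float]:
        """Each clade occupies a contiguous window of metagenomes.

        Windows of successive clades are staggered so clades overlap in the
        middle of the series but each also has metagenomes where it is
        absent, giving every genome both detected and undetected samples.
        """
        mids = self.metagenome_ids
        plan: dict[tuple[str, str], float] = {}
        n = len(mids)
        for k, (clade, _cls, _cnt) in enumerate(self.clade_plan):
            width = max(2, n - 3)
            start = min(k * 3, max(0, n - width))
            cov = 20.0 - 4.0 * k
            for j, m in enumerate(mids):
                plan[(clade, m)] = cov if start <= j < start + width else 0.0
        return plan


@dataclass
class TruthTable:
    """Planted truth: family and environmental label per gene, bin per
    family, and detection per genome x metagenome."""

    family_of_gene: dict[str, str]
    bin_of_family: dict[str, PangenomeBin]
    env_label_of_gene: dict[str, EnvClass]
    detection: dict[tuple[str, str], bool]
    island_families: list[str]

    @property
    def n_families(self) -> int:
        return len(self.bin_of_family)

    def bin_of_gene(self, gene_id: str) -> PangenomeBin:
        return self.bin_of_family[self.family_of_gene[gene_id]]


@dataclass
class SyntheticProject:
    params: SimulationParams
    genomes: list[Genome]
    annotations: list[AnnotationRecord]
    truth: TruthTable
    family_aa: dict[str, dict[str, str]]  # family -> gene_id -> aa seq


def _random_aa(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(AA_ALPHABET), size=length))


def _mutate(rng: np.random.Generator, seq: str, identity: float) -> str:
    out = list(seq)
    for i, c in enumerate(out):
        if rng.random() > identity:
            choices = AA_ALPHABET.replace(c, "")
            out[i] = choices[rng.integers(len(choices))]
    return "".join(out)


def _back_translate(aa: str) -> str:
    return "".join(_CODON[c] for c in aa) + _STOP


def simulate_pangenome(
    params: SimulationParams | None = None,
) -> SyntheticProject:
    """Generate genomes, gene families, annotations and the truth table.

    Family plan: ``CORE`` families occur once in every genome; ``HLC``/
    ``LLC`` families in every genome of that light class only; ``SNG``
    families in exactly one genome; ``OTH`` families in a random subset of
    2..n-1 genomes (redrawn if the subset coincides with a whole light
    class); ``ISL`` families occur in every genome and their genes form the
    contiguous island blocks.
    """
    params = (params or SimulationParams()).validate()
    rng = np.random.default_rng(params.rng_seed)

    genome_ids: list[str] = []
    clade_of: dict[str, str] = {}
    class_of: dict[str, str] = {}
    for clade, cls, count in params.clade_plan:
        for i in range(count):
            gid = f"{clade}_{i + 1:02d}"
            genome_ids.append(gid)
            clade_of[gid] = clade
            class_of[gid] = cls
    if len(set(genome_ids)) != len(genome_ids):
        raise MetapanError("duplicate genome ids in clade plan")

    hl = [g for g in genome_ids if class_of[g] == "HL"]
    ll = [g for g in genome_ids if class_of[g] == "LL"]
    n = len(genome_ids)

    # ---- family plan: (family_id, bin, member genomes, is_island)
    families: list[tuple[str, PangenomeBin, list[str], bool]] = []
    all_bin = PangenomeBin.CORE_ALL if n > 1 else PangenomeBin.SINGLETON
    for f in range(params.n_core_families):
        families.append((f"CORE_{f:04d}", all_bin, list(genome_ids), False))
    n_island_families = params.islands_per_genome * params.island_len
    for f in range(n_island_families):
        families.append((f"ISL_{f:04d}", all_bin, list(genome_ids), True))
    if hl and ll:
        for f in range(params.n_clade_core_families):
            families.append((f"HLC_{f:04d}", PangenomeBin.CORE_HL, list(hl), False))
            families.append((f"LLC_{f:04d}", PangenomeBin.CORE_LL, list(ll), False))
    for g_idx, gid in enumerate(genome_ids):
        for f in range(params.n_singletons_per_genome):
            families.append(
                (f"SNG_{g_idx:02d}_{f:04d}", PangenomeBin.SINGLETON, [gid], False)
            )
    for f in range(params.n_other_families):
        if n < 4:
            break
        while True:
            size = int(rng.integers(2, n))  # 2..n-1
            members = sorted(rng.choice(genome_ids, size=size, replace=False))
            if set(members) not in (set(hl), set(ll)):
                break
        families.append((f"OTH_{f:04d}", PangenomeBin.OTHER, members, False))

    # ---- sequences
    ancestors = {
        fid: _random_aa(rng, int(rng.integers(*params.aa_len_range)))
        for fid, _, _, _ in families
    }
    family_aa: dict[str, dict[str, str]] = {fid: {} for fid, _, _, _ in families}

    family_of_gene: dict[str, str] = {}
    bin_of_family = {fid: b for fid, b, _, _ in families}
    island_families = [fid for fid, _, _, isl in families if isl]

    per_genome_genes: dict[str, list[tuple[str, str, str]]] = {
        g: [] for g in genome_ids
    }  # genome -> [(gene placeholder id, family, aa)]
    counters = {g: 0 for g in genome_ids}
    for fid, _bin, members, _isl in families:
        for gid in members:
            counters[gid] += 1
            gene_id = f"{gid}_g{counters[gid]:04d}"
            aa = _mutate(rng, ancestors[fid], params.within_identity)
            per_genome_genes[gid].append((gene_id, fid, aa))
            family_of_gene[gene_id] = fid
            family_aa[fid][gene_id] = aa

    # ---- layout: shuffle non-island genes, insert island blocks contiguously
    genomes: list[Genome] = []
    for gid in genome_ids:
        genes = per_genome_genes[gid]
        island = [g for g in genes if g[1].startswith("ISL_")]
        regular = [g for g in genes if not g[1].startswith("ISL_")]
        if len(island) > len(genes):
            raise MetapanError("more island genes than genome genes")
        order = list(rng.permutation(len(regular)))
        laid = [regular[i] for i in order]
        for b in range(params.islands_per_genome):
            block = island[b * params.island_len : (b + 1) * params.island_len]
            pos = int(rng.integers(0, len(laid) + 1))
            laid[pos:pos] = block
        contig_id = f"{gid}_c1"
        seq_parts: list[str] = []
        calls: list[GeneCall] = []
        cursor = 0
        spacer = "".join(rng.choice(list("ACGT"), size=params.intergenic_len))
        seq_parts.append(spacer)
        cursor += params.intergenic_len
        for gene_id, fid, aa in laid:
            nt = _back_translate(aa)
            calls.append(
                GeneCall(
                    gene_id=gene_id,
                    genome_id=gid,
                    contig_id=contig_id,
                    start=cursor,
                    stop=cursor + len(nt),
                    strand="+",
                    partial=False,
                    aa_seq=aa,
                )
            )
            seq_parts.append(nt)
            cursor += len(nt)
            spacer = "".join(rng.choice(list("ACGT"), size=params.intergenic_len))
            seq_parts.append(spacer)
            cursor += params.intergenic_len
        genomes.append(
            Genome(
                genome_id=gid,
                clade_label=clade_of[gid],
                light_class=class_of[gid],
                contigs=[(contig_id, cursor)],
                genes=calls,
            )
        )

    # ---- detection truth and environmental truth
    plan = params.abundance_plan or params.default_abundance_plan()
    detection: dict[tuple[str, str], bool] = {}
    detected_any: dict[str, bool] = {}
    for gid in genome_ids:
        any_det = False
        for m in params.metagenome_ids:
            cov = plan.get((clade_of[gid], m), 0.0)
            detection[(gid, m)] = cov > 0
            any_det = any_det or cov > 0
        detected_any[gid] = any_det

    env_label_of_gene: dict[str, EnvClass] = {}
    for gid in genome_ids:
        for g in per_genome_genes[gid]:
            gene_id, fid, _ = g
            if not detected_any[gid]:
                env_label_of_gene[gene_id] = EnvClass.UNCLASSIFIED
            elif fid.startswith("ISL_"):
                env_label_of_gene[gene_id] = EnvClass.EAG
            else:
                env_label_of_gene[gene_id] = EnvClass.ECG

    # ---- annotations: one function per family, most genes annotated
    annotations: list[AnnotationRecord] = []
    for fid, _b, _m, _isl in families:
        for gene_id in sorted(family_aa[fid]):
            if rng.random() < params.annotation_prob:
                annotations.append(
                    AnnotationRecord(
                        gene_id=gene_id,
                        source="COG",
                        accession=f"COG_{fid}",
                        function_text=f"function of family {fid}",
                    )
                )

    truth = TruthTable(
        family_of_gene=family_of_gene,
        bin_of_family=bin_of_family,
        env_label_of_gene=env_label_of_gene,
        detection=detection,
        island_families=island_families,
    )
    return SyntheticProject(
        params=params,
        genomes=genomes,
        annotations=annotations,
        truth=truth,
        family_aa=family_aa,
    )


def simulate_coverage(project: SyntheticProject) -> list[CoverageProfile]:
    """Per-metagenome coverage profiles consistent with the planted truth.

    Where a genome is present (plan coverage > 0) its genes draw mean
    coverages around the planned abundance with the configured dispersion,
    island genes are multiplied by the island multiplier, and breadth is
    the 'detected' constant; where absent, coverage is 0 and breadth is the
    'undetected' constant. Mapped read counts follow coverage x genome
    length / read length.
    """
    params = project.params
    rng = np.random.default_rng(params.rng_seed + 1)
    plan = params.abundance_plan or params.default_abundance_plan()
    clade_of = {g.genome_id: g.clade_label for g in project.genomes}

    profiles = []
    for m in params.metagenome_ids:
        mean_cov: dict[str, float] = {}
        breadth: dict[str, float] = {}
        mapped: dict[str, int] = {}
        for genome in project.genomes:
            a = plan.get((clade_of[genome.genome_id], m), 0.0)
            if a > 0:
                breadth[genome.genome_id] = params.detected_breadth
                for gene in genome.genes:
                    c = a
                    if params.coverage_dispersion > 0:
                        c = max(
                            0.0,
                            rng.normal(a, params.coverage_dispersion * a),
                        )
                    fid = project.truth.family_of_gene[gene.gene_id]
                    if fid.startswith("ISL_"):
                        c *= params.island_multiplier
                    mean_cov[gene.gene_id] = c
                mapped[genome.genome_id] = int(
                    round(a * genome.total_length / params.read_len)
                )
            else:
                breadth[genome.genome_id] = params.undetected_breadth
                for gene in genome.genes:
                    mean_cov[gene.gene_id] = 0.0
                mapped[genome.genome_id] = 0
        profiles.append(
            CoverageProfile(
                metagenome_id=m,
                mean_coverage=mean_cov,
                breadth=breadth,
                mapped_read_counts=mapped,
                total_reads=params.total_reads_per_metagenome,
            )
        )
    return profiles


# ---------------------------------------------------------------------------
# Evaluation against truth

def evaluate_against_truth(
    truth: TruthTable,
    clusters: list[GeneCluster] | None = None,
    env_labels: dict[str, EnvClass] | None = None,
    cluster_bins: dict[str, PangenomeBin] | None = None,
) -> dict[str, float]:
    """Compare predictions with the planted truth.

    Returns whichever of these apply: ``ari`` (adjusted Rand index of the
    predicted partition vs planted families), ``bin_accuracy`` (fraction of
    genes whose cluster's bin equals the planted family bin), and
    ``eag_precision`` / ``eag_recall`` of EAG calls over genes whose planted
    label is not UNCLASSIFIED.
    """
    from sklearn.metrics import adjusted_rand_score

    metrics: dict[str, float] = {}
    if clusters is not None:
        gene_ids = sorted(truth.family_of_gene)
        predicted = {g: c.cluster_id for c in clusters for g in c.member_gene_ids}
        if set(predicted) != set(gene_ids):
            raise MetapanError("predicted clustering covers a different gene set")
        metrics["ari"] = float(
            adjusted_rand_score(
                [truth.family_of_gene[g] for g in gene_ids],
                [predicted[g] for g in gene_ids],
            )
        )
        if cluster_bins is not None:
            ok = total = 0
            for c in clusters:
                for g in c.member_gene_ids:
                    total += 1
                    if cluster_bins[c.cluster_id] == truth.bin_of_gene(g):
                        ok += 1
            metrics["bin_accuracy"] = ok / total
    if env_labels is not None:
        tp = fp = fn = 0
        for g, t in truth.env_label_of_gene.items():
            if t is EnvClass.UNCLASSIFIED:
                continue
            p = env_labels.get(g)
            if p is None:
                raise MetapanError(f"no predicted env label for gene {g!r}")
            if p is EnvClass.EAG and t is EnvClass.EAG:
                tp += 1
            elif p is EnvClass.EAG and t is not EnvClass.EAG:
                fp += 1
            elif p is not EnvClass.EAG and t is EnvClass.EAG:
                fn += 1
        metrics["eag_precision"] = tp / (tp + fp) if tp + fp else 1.0
        metrics["eag_recall"] = tp / (tp + fn) if tp + fn else 1.0
    return metrics


# ---------------------------------------------------------------------------
# On-disk project

def write_project(
    project: SyntheticProject,
    profiles: list[CoverageProfile],
    out_dir: str | Path,
) -> Path:
    """Write the project in exactly the formats the pipeline ingests.

    Emits per-genome FASTA/gene-calls/amino-acid FASTA, genomes.tsv,
    clade_map.tsv, annotations.tsv, a coverage/ table bundle and the truth
    tables. Re-running with the same project yields byte-identical files.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    # Contig sequences are rebuilt from the gene calls with fixed 'A' filler
    # in intergenic gaps; only gene spans matter downstream.
    genomes_tsv = out / "genomes.tsv"
    with open(genomes_tsv, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["genome_id", "clade", "fasta", "gene_calls", "aa_fasta"])
        for genome in project.genomes:
            gid = genome.genome_id
            contig_seqs: dict[str, list[str]] = {
                cid: ["A"] * length for cid, length in genome.contigs
            }
            aa_seqs: dict[str, str] = {}
            for gene in genome.genes:
                nt = _back_translate(gene.aa_seq)
                contig_seqs[gene.contig_id][gene.start : gene.stop] = list(nt)
                aa_seqs[gene.gene_id] = gene.aa_seq
            io_formats.write_fasta(
                {cid: "".join(chars) for cid, chars in contig_seqs.items()},
                out / f"{gid}.fa",
            )
            io_formats.write_gene_calls(genome.genes, out / f"{gid}_calls.tsv")
            io_formats.write_fasta(aa_seqs, out / f"{gid}.faa")
            w.writerow([gid, genome.clade_label, f"{gid}.fa",
                        f"{gid}_calls.tsv", f"{gid}.faa"])

    clades = sorted({(g.clade_label, g.light_class) for g in project.genomes})
    with open(out / "clade_map.tsv", "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["clade", "light_class"])
        for clade, cls in clades:
            w.writerow([clade, cls])

    io_formats.write_annotations(project.annotations, out / "annotations.tsv")
    recruitment.write_coverage_tables(profiles, out / "coverage")

    with open(out / "truth.tsv", "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["gene_id", "family_id", "family_bin", "env_label"])
        for gene_id in sorted(project.truth.family_of_gene):
            fid = project.truth.family_of_gene[gene_id]
            w.writerow(
                [gene_id, fid, project.truth.bin_of_family[fid].value,
                 project.truth.env_label_of_gene[gene_id].value]
            )
    with open(out / "truth_detection.tsv", "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["genome_id", "metagenome_id", "detected"])
        for (gid, m), det in sorted(project.truth.detection.items()):
            w.writerow([gid, m, int(det)])
    return out


# ---------------------------------------------------------------------------
# Per-position read fixture for the BAM backend

@dataclass
class ReadFixture:
    """A tiny per-position fixture: reference contigs, aligned reads as SAM
    text, gene calls, and independently computed (brute force) depth
    vectors and the exact coverage profile they imply."""

    genome: Genome
    contig_seqs: dict[str, str]
    sam_text: str
    depth_vectors: dict[str, np.ndarray]
    profile: CoverageProfile


def simulate_read_fixture(seed: int = 0, n_reads: int = 50,
                          read_len: int = 50) -> ReadFixture:
    """Three contigs, ~50 uniformly placed reads, and the exact pileup.

    Depth vectors are accumulated by brute force (one numpy add per read),
    independent of any alignment library, so they can serve as the oracle
    for the BAM backend.
    """
    rng = np.random.default_rng(seed)
    lengths = {"fix_c1": 420, "fix_c2": 300, "fix_c3": 360}
    contig_seqs = {
        cid: "".join(rng.choice(list("ACGT"), size=ln))
        for cid, ln in lengths.items()
    }
    genes = []
    spans = {
        "fix_c1": [(30, 210), (240, 390)],
        "fix_c2": [(60, 240)],
        "fix_c3": [(0, 150), (180, 330)],
    }
    i = 0
    for cid in sorted(spans):
        for start, stop in spans[cid]:
            i += 1
            genes.append(
                GeneCall(
                    gene_id=f"fix_g{i:02d}", genome_id="FIXG", contig_id=cid,
                    start=start, stop=stop, strand="+", partial=True,
                    aa_seq="M" * ((stop - start) // 3 - 1),
                )
            )
    genome = Genome(
        genome_id="FIXG", clade_label="FIX", light_class="other",
        contigs=sorted(lengths.items()), genes=genes,
    )

    depth = {cid: np.zeros(ln) for cid, ln in lengths.items()}
    sam_lines = [f"@HD\tVN:1.6\tSO:coordinate"]
    for cid in sorted(lengths):
        sam_lines.append(f"@SQ\tSN:{cid}\tLN:{lengths[cid]}")
    placements = []
    cids = sorted(lengths)
    for r in range(n_reads):
        cid = cids[int(rng.integers(len(cids)))]
        pos = int(rng.integers(0, lengths[cid] - read_len + 1))
        placements.append((cid, pos, r))
        depth[cid][pos : pos + read_len] += 1.0
    placements.sort(key=lambda t: (t[0], t[1], t[2]))
    for cid, pos, r in placements:
        seq = contig_seqs[cid][pos : pos + read_len]
        sam_lines.append(
            "\t".join(
                [f"read_{r:03d}", "0", cid, str(pos + 1), "60",
                 f"{read_len}M", "*", "0", "0", seq, "I" * read_len]
            )
        )
    profile = recruitment.profile_depth_vectors(
        depth, [genome], "fixture_mg",
        mapped_read_counts={"FIXG": n_reads}, total_reads=1000,
    )
    return ReadFixture(
        genome=genome,
        contig_seqs=contig_seqs,
        sam_text="\n".join(sam_lines) + "\n",
        depth_vectors=depth,
        profile=profile,
    )
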