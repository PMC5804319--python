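"""Environmental core/accessory classification and its aggregations."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from metapan import envclass
from metapan.model import (
    AnalysisParams,
    AnnotationRecord,
    EnvClass,
    EnvLabel,
    GeneCall,
    Genome,
    MetapanError,
)
from metapan.recruitment import DetectionTable


def _genome(gene_ids: list[str], gid: str = "G") -> Genome:
    genes = [
        GeneCall(gene_id=g, genome_id=gid, contig_id=f"{gid}_c", start=i * 30,
                 stop=i * 30 + 30, strand="+", aa_seq="M" * 9)
        for i, g in enumerate(gene_ids)
    ]
    return Genome(genome_id=gid, contigs=[(f"{gid}_c", 30 * len(gene_ids))],
                  genes=genes)


def _detection(genomes: list[str], detected_in: dict[str, list[str]],
               metagenomes: list[str]) -> DetectionTable:
    breadth = pd.DataFrame(0.0, index=genomes, columns=metagenomes)
    det = pd.DataFrame(False, index=genomes, columns=metagenomes)
    for g, mids in detected_in.items():
        for m in mids:
            det.loc[g, m] = True
            breadth.loc[g, m] = 0.9
    return DetectionTable(breadth=breadth, detected=det)


class TestClassify:
    def test_median_rule_marks_low_coverage_gene(self):
        genome = _genome(["g1", "g2", "g3", "g4"])
        det = _detection(["G"], {"G": ["m1"]}, ["m1"])
        cov = {"g1": {"m1": 100.0}, "g2": {"m1": 80.0},
               "g3": {"m1": 40.0}, "g4": {"m1": 9.0}}
        labels = {l.gene_id: l.label
                  for l in envclass.classify_genes_env(cov, det, genome)}
        # sums {100, 80, 40, 9}: median 60, cutoff 15 -> only g4 below
        assert labels == {"g1": EnvClass.ECG, "g2": EnvClass.ECG,
                          "g3": EnvClass.ECG, "g4": EnvClass.EAG}

    def test_exactly_quarter_of_median_is_ecg(self):
        genome = _genome(["g1", "g2", "g3"])
        det = _detection(["G"], {"G": ["m1"]}, ["m1"])
        cov = {"g1": {"m1": 40.0}, "g2": {"m1": 40.0}, "g3": {"m1": 10.0}}
        # median 40, cutoff 10: g3 sits exactly at the cutoff -> ECG (strict <)
        labels = {l.gene_id: l.label
                  for l in envclass.classify_genes_env(cov, det, genome)}
        assert labels["g3"] == EnvClass.ECG

    def test_undetected_genome_is_all_unclassified(self):
        genome = _genome(["g1", "g2"])
        det = _detection(["G"], {}, ["m1", "m2"])
        labels = envclass.classify_genes_env({}, det, genome)
        assert all(l.label is EnvClass.UNCLASSIFIED for l in labels)
        assert all(l.coverage_sum == 0.0 for l in labels)

    def test_missing_coverage_cell_is_fatal(self):
        genome = _genome(["g1"])
        det = _detection(["G"], {"G": ["m1", "m2"]}, ["m1", "m2"])
        with pytest.raises(MetapanError, match="m2"):
            envclass.classify_genes_env({"g1": {"m1": 5.0}}, det, genome)

    def test_scaling_coverages_preserves_labels(self):
        rng = np.random.default_rng(31)
        genome = _genome([f"g{i}" for i in range(20)])
        det = _detection(["G"], {"G": ["m1", "m2"]}, ["m1", "m2"])
        base = {
            f"g{i}": {"m1": float(rng.uniform(0, 30)),
                      "m2": float(rng.uniform(0, 30))}
            for i in range(20)
        }
        ref = [l.label for l in envclass.classify_genes_env(base, det, genome)]
        for scale in (0.01, 7.3, 1000.0):
            scaled = {g: {m: v * scale for m, v in row.items()}
                      for g, row in base.items()}
            got = [l.label for l in envclass.classify_genes_env(scaled, det, genome)]
            assert got == ref

    def test_undetected_metagenomes_do_not_contribute(self):
        genome = _genome(["g1", "g2"])
        det1 = _detection(["G"], {"G": ["m1"]}, ["m1"])
        det2 = _detection(["G"], {"G": ["m1"]}, ["m1", "m2"])
        cov = {"g1": {"m1": 10.0, "m2": 500.0}, "g2": {"m1": 10.0, "m2": 0.0}}
        l1 = envclass.classify_genes_env(cov, det1, genome)
        l2 = envclass.classify_genes_env(cov, det2, genome)
        assert [(l.label, l.coverage_sum) for l in l1] == [
            (l.label, l.coverage_sum) for l in l2
        ]

    def test_label_counts_conserve_total(self, env_labels, project):
        n_total = sum(g.n_genes for g in project.genomes)
        assert len(env_labels) == n_total
        by_genome: dict[str, int] = {}
        for l in env_labels:
            by_genome[l.genome_id] = by_genome.get(l.genome_id, 0) + 1
        for g in project.genomes:
            assert by_genome[g.genome_id] == g.n_genes


class TestEagFraction:
    def _labels(self, gid, n_eag, n_ecg, n_un=0):
        mk = lambda i, lab: EnvLabel(gene_id=f"{gid}_{lab.value}{i}", genome_id=gid,
                                     label=lab, coverage_sum=1.0,
                                     genome_median_sum=1.0)
        return ([mk(i, EnvClass.EAG) for i in range(n_eag)]
                + [mk(i, EnvClass.ECG) for i in range(n_ecg)]
                + [mk(i, EnvClass.UNCLASSIFIED) for i in range(n_un)])

    def test_ten_percent(self):
        out = envclass.eag_fraction_per_genome(self._labels("G", 10, 90))
        assert out["G"] == pytest.approx(0.10)

    def test_all_ecg_is_zero(self):
        assert envclass.eag_fraction_per_genome(self._labels("G", 0, 5)) == {"G": 0.0}

    def test_all_unclassified_reports_missing(self):
        out = envclass.eag_fraction_per_genome(self._labels("G", 0, 0, 5))
        assert out["G"] is None

    def test_matches_planted_island_fraction(self, env_labels, project):
        """Mean EAG fraction across detected genomes equals the planted
        island share of each genome's genes (multiplier 0 -> exact)."""
        fractions = envclass.eag_fraction_per_genome(env_labels)
        p = project.params
        n_island = p.islands_per_genome * p.island_len
        for genome in project.genomes:
            frac = fractions[genome.genome_id]
            planted = n_island / genome.n_genes
            assert frac == pytest.approx(planted, abs=1e-12)


class TestFunctionConnectivity:
    def _ann(self, gid, acc="F1"):
        return AnnotationRecord(gene_id=gid, source="COG", accession=acc,
                                function_text=f"fn {acc}")

    def _label(self, gid, lab):
        return EnvLabel(gene_id=gid, genome_id="G", label=lab,
                        coverage_sum=1.0, genome_median_sum=1.0)

    def test_ratio(self):
        labels = [self._label("a", EnvClass.EAG), self._label("b", EnvClass.EAG),
                  self._label("c", EnvClass.EAG), self._label("d", EnvClass.ECG)]
        anns = [self._ann(g) for g in "abcd"]
        (fc,) = envclass.function_env_connectivity(labels, anns)
        assert fc.n_eag == 3 and fc.n_ecg == 1 and fc.eag_ratio == 0.75

    def test_unclassified_only_function_excluded(self):
        labels = [self._label("a", EnvClass.UNCLASSIFIED)]
        anns = [self._ann("a")]
        assert envclass.function_env_connectivity(labels, anns) == []

    def test_ranking_stable_under_permutation(self, env_labels, project):
        rng = np.random.default_rng(13)
        ref = envclass.function_env_connectivity(env_labels, project.annotations)
        for _ in range(3):
            labs = [env_labels[i] for i in rng.permutation(len(env_labels))]
            anns = [project.annotations[i]
                    for i in rng.permutation(len(project.annotations))]
            assert envclass.function_env_connectivity(labs, anns) == ref

    def test_island_functions_rank_top(self, env_labels, project):
        top = envclass.function_env_connectivity(env_labels, project.annotations)
        n_island = len(project.truth.island_families)
        island_accessions = {f"COG_{fid}" for fid in project.truth.island_families}
        assert {f.accession for f in top[:n_island]} == island_accessions
        assert all(f.eag_ratio == 1.0 for f in top[:n_island])


class TestEagRuns:
    def _run_genome_labels(self, pattern: str):
        genome = _genome([f"g{i}" for i in range(len(pattern))])
        labels = [
            EnvLabel(gene_id=f"g{i}", genome_id="G",
                     label=EnvClass.EAG if c == "A" else EnvClass.ECG,
                     coverage_sum=1.0, genome_median_sum=1.0)
            for i, c in enumerate(pattern)
        ]
        return genome, labels

    def test_single_run(self):
        genome, labels = self._run_genome_labels("EEAAAE")
        assert envclass.eag_runs(genome, labels) == [("G_c", 2, 3)]

    def test_no_eags(self):
        genome, labels = self._run_genome_labels("EEEE")
        assert envclass.eag_runs(genome, labels) == []

    def test_run_at_end_is_closed(self):
        genome, labels = self._run_genome_labels("EAA")
        assert envclass.eag_runs(genome, labels) == [("G_c", 1, 2)]

    def test_missing_label_is_fatal(self):
        genome, labels = self._run_genome_labels("EA")
        with pytest.raises(MetapanError, match="g1"):
            envclass.eag_runs(genome, labels[:1])

    def test_planted_islands_recovered_as_modal_run_length(
        self, env_labels, project
    ):
        by_genome: dict[str, list] = {}
        for l in env_labels:
            by_genome.setdefault(l.genome_id, []).append(l)
        lengths = []
        for genome in project.genomes:
            runs = envclass.eag_runs(genome, by_genome[genome.genome_id])
            lengths.extend(r[2] for r in runs)
        values, counts = np.unique(lengths, return_counts=True)
        mode = int(values[counts.argmax()])
        assert mode == project.params.island_len


def test_env_labels_round_trip(env_labels, tmp_path):
    envclass.write_env_labels(env_labels, tmp_path / "labels.tsv")
    back = envclass.read_env_labels(tmp_path / "labels.tsv")
    key = lambda l: (l.genome_id, l.gene_id)
    orig = sorted(env_labels, key=key)
    got = sorted(back, key=key)
    assert [(l.gene_id, l.label) for l in got] == [(l.gene_id, l.label) for l in orig]
    for a, b in zip(got, orig):
        assert a.coverage_sum == pytest.approx(b.coverage_sum, rel=1e-5)
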