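from __future__ import annotations

import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # reference_impls importable

from metapan import envclass, homology, mcl, pangenome, recruitment
from metapan.synthetic_data import (
    SimulationParams,
    simulate_coverage,
    simulate_pangenome,
)


@pytest.fixture(scope="session")
def project():
    """The default synthetic project (8 genomes, 2 clades, seed 42)."""
    return simulate_pangenome(SimulationParams())


@pytest.fixture(scope="session")
def profiles(project):
    return simulate_coverage(project)


@pytest.fixture(scope="session")
def all_genes(project):
    return [g for genome in project.genomes for g in genome.genes]


@pytest.fixture(scope="session")
def clusters(all_genes):
    """Gene clusters recovered end-to-end from sequences (search -> MCL)."""
    hits = homology.all_vs_all_search(all_genes)
    self_scores = homology.compute_self_scores(all_genes)
    edges = homology.build_minbit_graph(hits, self_scores)
    matrix = mcl.build_stochastic_matrix(edges, [g.gene_id for g in all_genes])
    return mcl.mcl_cluster(matrix)


@pytest.fixture(scope="session")
def occurrence(clusters, project):
    return pangenome.build_occurrence(clusters, project.genomes)


@pytest.fixture(scope="session")
def bins(occurrence, project):
    return pangenome.assign_bins(
        occurrence, {g.genome_id: g.light_class for g in project.genomes}
    )


@pytest.fixture(scope="session")
def detection(profiles):
    return recruitment.build_detection_table(profiles)


@pytest.fixture(scope="session")
def env_labels(project, profiles, detection):
    gene_cov: dict[str, dict[str, float]] = {}
    for p in profiles:
        for gid, c in p.mean_coverage.items():
            gene_cov.setdefault(gid, {})[p.metagenome_id] = c
    labels = []
    for genome in project.genomes:
        labels.extend(envclass.classify_genes_env(gene_cov, detection, genome))
    return labels


@pytest.fixture(scope="session")
def written_project(tmp_path_factory, project, profiles):
    from metapan.synthetic_data import write_project

    out = tmp_path_factory.mktemp("simproj")
    write_project(project, profiles, out)
    return out
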