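"""Occurrence bins and genome relationships from a cluster partition.

Tabulates gene clusters across genomes, assigns the five occurrence bins
(core to all, core to the HL or LL clade, singleton, other), and orders
genomes by Ward clustering on shared gene-cluster presence.
"""

from collections import Counter

from metapan import homology, io_formats, mcl, pangenome
from metapan.synthetic_data import SimulationParams, simulate_pangenome

project = simulate_pangenome(SimulationParams(rng_seed=3))
genes = [g for genome in project.genomes for g in genome.genes]

hits = homology.all_vs_all_search(genes)
edges = homology.build_minbit_graph(hits, homology.compute_self_scores(genes))
clusters = mcl.mcl_cluster(
    mcl.build_stochastic_matrix(edges, [g.gene_id for g in genes])
)

occ = pangenome.build_occurrence(clusters, project.genomes)
bins = pangenome.assign_bins(
    occ, {g.genome_id: g.light_class for g in project.genomes}
)
counts = Counter(b.bin.value for b in bins)
print("bin sizes:", dict(sorted(counts.items())))
print("sum of bins == clusters:", sum(counts.values()) == len(clusters))

rates = pangenome.annotation_rate(bins, clusters, project.annotations, "COG")
print("annotation rate per bin:",
      {b: f"{r:.0%}" for b, r in rates.items()})

tree = pangenome.cluster_genomes(occ)
print("genome order (Ward on shared clusters):", ", ".join(tree.leaf_order()))
print("newick:", io_formats.dendrogram_to_newick(tree)[:70], "...")
# Genomes of the same clade sit next to each other: shared gene content
# recovers the clade structure without any marker-gene phylogeny.
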