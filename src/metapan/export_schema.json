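{
  "schema_version": "metapan-export-1",
  "required": ["schema_version", "clusters", "genomes", "genome_tree", "cluster_tree"],
  "cluster_record_required": [
    "cluster_id", "bin", "genomes_present", "n_genes",
    "n_ecg", "n_eag", "n_unclassified", "eag_ratio", "occurrence"
  ],
  "genome_record_required": ["genome_id", "detection", "breadth", "relative_distribution"]
}
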