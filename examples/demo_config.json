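{
  "seed": 11,
  "outdir": "curdcat_demo_run",
  "simulate": {
    "n_genomes": 6,
    "genome_length_bp": 20000,
    "n_variants": 1,
    "strain_rate": 0.002,
    "timepoints": ["week2", "week4", "week13"],
    "n_mges": 12,
    "n_switching": 2,
    "n_bins": 6,
    "redundancy": {"n_unique": 10, "n_contained": 4, "n_partial": 2},
    "pangenome": {
      "n_group_a": 12,
      "n_group_b": 12,
      "n_core": 30,
      "n_enriched": 10,
      "n_null": 100
    }
  },
  "associate": {"min_links": 5, "dominance_ratio": 3.0}
}
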