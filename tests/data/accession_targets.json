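{
  "description": "Regression targets for the deposited D. melanogaster lbe/lbl accession set. These values are only checked when a locally fetched accession data directory is available (see scripts/fetch_accessions.py); they are not part of the desk-scale test suite.",
  "loci": {
    "lbe": {
      "accessions": ["FJ754496", "FJ754564"],
      "pi_all_sites": 0.0056,
      "rm": 10,
      "fst_haplotype_groups": 0.84,
      "gc_percent": 59.5,
      "sawyer_mean_fragment_bp": 1202
    },
    "lbl": {
      "accessions": ["FJ754565", "FJ754633"],
      "rm": 14,
      "fst_haplotype_groups": 0.86,
      "gc_percent": 51.3,
      "sawyer_mean_fragment_bp": 703,
      "m0_vs_m3_lrt": 45.37
    }
  },
  "tolerances": {
    "pi": 0.0005,
    "fst": 0.02,
    "gc_percent": 0.5,
    "sawyer_mean_fragment_bp": 100,
    "lrt": 2.0
  },
  "estimator_variant_grid": {
    "jukes_cantor": [false, true],
    "fst_variant": ["hsm", "pi-ratio"],
    "frequencies": ["f3x4", "f61"]
  }
}
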