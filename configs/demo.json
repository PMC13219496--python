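{
  "chromsizes": {"chrI": 900000, "chrII": 800000, "chrIII": 700000, "chrIV": 900000},
  "pairs": [
    {"pair_id": "pair1", "chrom_a": "chrI", "pos_a": 200000, "chrom_b": "chrI", "pos_b": 600000},
    {"pair_id": "pair2", "chrom_a": "chrII", "pos_a": 400000, "chrom_b": "chrIII", "pos_b": 350000},
    {"pair_id": "pair3", "chrom_a": "chrIV", "pos_a": 200000, "chrom_b": "chrIV", "pos_b": 600000}
  ],
  "bin_size": 10000,
  "p_plus": 0.65,
  "p_minus": 0.02,
  "ratios": [0.0, 0.25, 0.5, 0.75, 1.0],
  "n_cells": 2000,
  "n_contacts": 18000000,
  "n_hic_replicates": 2,
  "detection_p_grid": [0.02, 0.05, 0.1, 0.2],
  "detection_n_reps": 10,
  "run_detection": true,
  "seed": 1
}
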