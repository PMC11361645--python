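{
  "description": "Published rate constants for Arabidopsis TTN5 (wild type and the T30N and Q70L point mutants): second-order association rates k_on (uM^-1 s^-1) and intrinsic dissociation rates k_off (s^-1) for the fluorescent nucleotide analogs mdGDP and mGppNHp, and intrinsic GTP hydrolysis rates k_cat (s^-1). Transcribed from the printed figure values; k_on null means no binding was observed for that pairing. For T30N/mGppNHp two dissociation rates were printed in different contexts; 0.004 is used and 0.026 kept as k_off_alternate.",
  "units": {"k_on": "uM^-1 s^-1", "k_off": "s^-1", "k_cat": "s^-1"},
  "reference_variant": "WT",
  "variants": {
    "WT": {
      "GDP": {"k_on": 0.044, "k_off": 0.012},
      "GppNHp": {"k_on": 0.029, "k_off": 0.001},
      "k_cat": 0.0015
    },
    "T30N": {
      "GDP": {"k_on": 0.048, "k_off": 0.149},
      "GppNHp": {"k_on": null, "k_off": 0.004, "k_off_alternate": 0.026},
      "k_cat": 0.0012
    },
    "Q70L": {
      "GDP": {"k_on": 0.401, "k_off": 0.025},
      "GppNHp": {"k_on": 0.222, "k_off": 0.006},
      "k_cat": 0.0007
    }
  },
  "printed_Kd_uM": {
    "WT": {"GDP": 0.267, "GppNHp": 0.029},
    "T30N": {"GDP": 3.091},
    "Q70L": {"GDP": 0.061, "GppNHp": 0.026}
  }
}
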