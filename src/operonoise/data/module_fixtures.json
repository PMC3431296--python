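{
  "version": 1,
  "expression": {
    "k_tx": 0.05,
    "delta_m": 0.005,
    "k_deg": 0.0003850817669777474,
    "mean_mrna": 10.0,
    "protein_levels": {"low": 53.0, "mid": 529.0, "high": 5285.0},
    "protein_levels_regulator_module": {"low": 1.0, "mid": 53.0, "high": 529.0}
  },
  "bursting": {"k_goff": 0.0028, "k_gon": 0.00045},
  "modules": {
    "linear_pathway": {
      "k_cat1": null, "k_cat2": 0.004, "K_m1": 100.0, "K_m2": 20.0,
      "S0": 1000.0, "k_out": 0.01, "ratio_target": 0.85
    },
    "redundant_enzymes": {
      "k_cat1": 0.002, "k_cat2": 0.002, "K_m1": 100.0, "K_m2": 100.0,
      "S0": 1000.0, "k_out": 0.01
    },
    "branch_point": {
      "k_cat1": 0.002, "k_cat2": 0.002, "K_m1": 20.0, "K_m2": 20.0,
      "k_out": 0.01, "ratio_target": 0.75, "bursting_default": false
    },
    "dual_regulators_or": {
      "V_max": 0.06667, "K_hill": null, "n_hill": 2.0
    },
    "physical_interaction": {
      "k_b": 0.001, "k_unb": 0.001
    },
    "covalent_modification": {
      "k_demod": 0.0076, "saturating": false
    },
    "covalent_modification_saturating": {
      "k_p": 0.004, "K_mA": 5.0, "k_demod": 1.9, "K_mAstar": 5.0,
      "saturating": true
    },
    "lac_reduced": {
      "lactose_levels_uM": {"minimal": 1.39, "mid": 83.0, "excess": 5000.0},
      "k_catY": 0.018, "K_mY": 50000.0,
      "k_catZ1": 0.02, "K_mZ1": 500.0,
      "k_catZ2": 0.02, "K_mZ2": 500.0,
      "n_repressor": 50, "k_rb": 0.0001, "k_ru": 0.01,
      "k_pb": 0.002, "k_pu": 0.005
    }
  }
}
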